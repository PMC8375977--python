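# Baseline U-Net conventions under which the published parameter totals are
# integer-exact (1,946,705 at 16 base filters; 31,054,145 at 64).
name: unet
input_size: 256
n_downsamples: 4
base_filters: [16, 64]
blocks_per_stage: 2
downsample: maxpool2x2
upsample: transposed_conv_2x2_bias_no_norm
normalization: batchnorm  # 4 parameters/channel incl. running statistics
head: conv1x1_sigmoid
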