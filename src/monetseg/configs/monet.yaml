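# Canonical MoNet configuration, frozen by the constrained width-resolution
# search: the unique configuration in the structural grammar (strictly
# increasing, at-most-doubling stage widths) whose parameter count equals
# the published total of 403,556.
name: monet
input_size: 256
n_downsamples: 2
widths: [20, 39, 66]
dilations: [4, 3, 2, 1]
dropout: 0.1
up_kernel: 3
normalized_up: true
residual: projection
extra_stem: false
extra_fuse: false
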