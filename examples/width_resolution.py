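"""Resolve MoNet's stage widths against the published parameter total.

Only the total (403,556) is published, not the per-stage widths. The
resolver enumerates a structural search space and reports every exact match
plus the nearest misses. The ratio-constrained default space contains no
exact match; the extended space (free integer widths, strictly increasing
and at most doubling per stage) contains exactly one, which is the
configuration frozen as canonical.
"""

from monetseg import resolve_monet_widths
from monetseg.architectures import (
    DOCUMENTED_SEARCH_SPACE,
    EXTENDED_SEARCH_SPACE,
)

TARGET = 403_556

doc = resolve_monet_widths(TARGET, DOCUMENTED_SEARCH_SPACE)
print(f"ratio-constrained space: {len(doc.exact)} exact matches")
for delta, count, cfg in doc.nearest[:3]:
    print(f"  nearest miss: widths={cfg.widths} up_kernel={cfg.up_kernel} "
          f"residual={cfg.residual} -> {count:,} (off by {delta})")

ext = resolve_monet_widths(TARGET, EXTENDED_SEARCH_SPACE)
print(f"extended space: {len(ext.exact)} exact match(es)")
for cfg in ext.exact:
    print(f"  widths={cfg.widths} up_kernel={cfg.up_kernel} "
          f"residual={cfg.residual} -> {TARGET:,} exactly")
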