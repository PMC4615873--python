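"""How the expression-adaptive solidity threshold is assembled.

A fixed count cutoff cannot work on RNA-seq: a 5x k-mer may be an error
on a 500x transcript but perfectly genuine on a 10x one. The corrector
therefore combines a k-mer-level threshold g(t) (scaled to the strongest
competing continuation t) with a read-level threshold h(r) (scaled to the
read's own expression tier) and applies f = min(g, h).
"""

from readfix import kmer_level_threshold, local_threshold, pair_read_threshold
from readfix.thresholds import drop_value

alpha = 0.05
print(f"alpha = {alpha} (variation coefficient)")
print("g(t) = alpha*t + 6*sqrt(alpha*t):")
for t in (0, 10, 100, 500, 5000):
    print(f"  t={t:>5}  g={kmer_level_threshold(t, alpha):8.2f}")

# A read whose k-mers sit on two expression tiers: a 500x gene body and
# a 20x spliced-in exon. The ladder finds the tier boundaries.
mults = [500] * 40 + [20] * 20
print("\nread-level threshold from sorted k-mer multiplicities "
      "(40 k-mers at 500x, 20 at 20x):")
for d in (1, 2):
    x = drop_value(mults, drop_factor=2.0, drop_index=d)
    print(f"  drop {d}: x={x:.0f}  h=g(x)={kmer_level_threshold(x, alpha):.1f}")
# Relaxing to the second drop admits the 20x exon's k-mers when the first
# attempt leaves the read over the correction budget.

t = 500
h = kmer_level_threshold(20, alpha)
print(f"\nf(t, r) = min(g(t), h): t={t}, h={h:.1f} -> "
      f"f={local_threshold(t, h, alpha):.1f}")
print("pair threshold = min(h1, h2):",
      f"{pair_read_threshold(29.4, 4.2):.1f}",
      "(the low-expression mate governs both)")
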