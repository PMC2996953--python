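"""Transposon-display dynamics in mutation-accumulation lines.

Simulates the assay design: 93 lines (46 where selfing occurred, 47 strictly
asexual) scored at 7 ancestral loci (4 heterozygous in the progenitor) over
~45 generations, with three replicate peak calls per cell.  Heterozygous
insertions segregate away during selfing with probability 1/4; somatic gains
show up as single-replicate calls.  The script recovers loss and somatic-gain
rates per treatment and compares them with Welch's t (one-sided,
sexual > asexual): losses should be near 4 x 0.25 / (7 x 45) ~ 0.0032 per
element per generation in sexuals and near zero in asexuals.
"""

from ltrkit import (
    TDSimConfig,
    expected_segregational_losses,
    loss_rate,
    simulate_td,
    somatic_gain_rate,
)

config = TDSimConfig()
td, manifest = simulate_td(config, seed=1)
print(f"{len(td.lines)} lines x {len(td.loci)} loci, {td.generations} generations")

losses = loss_rate(td, manifest["ancestral_loci"], treatment_order=("sexual", "asexual"))
gains = somatic_gain_rate(td, manifest["ancestral_loci"], treatment_order=("sexual", "asexual"))

print("\nLosses (per element per generation):")
for tr in ("sexual", "asexual"):
    print(f"  {tr:<8} {losses.mean[tr]:.5f} (+/- {losses.se[tr]:.5f}), n={losses.n[tr]}")
print(f"  Welch t = {losses.t:.2f}, one-sided p = {losses.p:.2g}")

print("\nPutative somatic gains (per element):")
for tr in ("sexual", "asexual"):
    print(f"  {tr:<8} {gains.mean[tr]:.5f} (+/- {gains.se[tr]:.5f})")

n_sexual = config.n_lines["sexual"]
expected = expected_segregational_losses(n_sexual, 0.25)
print(
    f"\nExpected segregational losses per heterozygous locus across "
    f"{n_sexual} selfed lines: {expected}"
)
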