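"""Build canonical pyranose conformers and classify their ring pucker.

Constructs the two chairs and the two skew-boats relevant to heparin at
ideal Cremer-Pople coordinates, measures the γ (C1-C2-C3-C4) and
δ (C1-O5-C5-C4) ring dihedrals, and classifies each ring with the ±23°
window rule. The printed (γ, δ) pairs are the classifier's reference
values; the designation column shows the purely geometric conformer name.
"""

from gagconf.pucker import classify_pucker, compute_gamma_delta
from gagconf.synthetic import build_pyranose_ring, canonical_cp, designate_ring

print(f"{'state':>6} {'theta':>6} {'phi2':>6} {'gamma':>8} {'delta':>8} "
      f"{'designated':>10} {'classified':>10}")
for state in ("4C1", "1C4", "2SO", "1S3"):
    cp = canonical_cp(state)
    ring = build_pyranose_ring(cp)
    gamma, delta = compute_gamma_delta(ring, 1)
    print(
        f"{state:>6} {cp.theta:6.0f} {cp.phi2:6.0f} {gamma:8.2f} {delta:8.2f} "
        f"{designate_ring(ring):>10} {classify_pucker(gamma, delta):>10}"
    )

# the planar ring sits outside every window -> "other" (noncanonical)
from gagconf.synthetic import CPParameters

flat = build_pyranose_ring(CPParameters(0.0, 0.0))
g, d = compute_gamma_delta(flat, 1)
print(f"planar ring: gamma={g:.2f}, delta={d:.2f} -> {classify_pucker(g, d)}")
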