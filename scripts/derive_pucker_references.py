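"""Regenerate src/gagconf/_pucker_refs.py from geometry.

The classifier's reference (γ, δ) values are not transcribed from any
figure: idealized rings are built at canonical Cremer–Pople coordinates
(chairs at θ = 0°/180°, skew-boats on the θ = 90° equator, located by the
ring-designation routine), their γ/δ dihedrals are measured, and the
results are frozen into a constants module. Run from the repository root:

    python scripts/derive_pucker_references.py
"""

from pathlib import Path

from gagconf.synthetic import (
    DEFAULT_Q,
    build_pyranose_ring,
    canonical_cp,
    designate_ring,
    ring_gamma_delta,
)

STATES = ("4C1", "1C4", "2SO", "1S3")

HEADER = '''"""Frozen pucker reference angles (degrees), derived geometrically.

Generated by scripts/derive_pucker_references.py — do not edit by hand.
Each reference is the (γ, δ) = (C1-C2-C3-C4, C1-O5-C5-C4) dihedral pair of
an idealized ring built at the canonical Cremer-Pople coordinates below
(Q = {q} Å). CANONICAL_CP maps state -> (Q, θ, φ2).
"""
'''


def main() -> None:
    refs: dict[str, tuple[float, float]] = {}
    cps: dict[str, tuple[float, float, float]] = {}
    for state in STATES:
        cp = canonical_cp(state, DEFAULT_Q)
        ring = build_pyranose_ring(cp)
        assert designate_ring(ring) == state
        gamma, delta = ring_gamma_delta(ring)
        refs[state] = (round(gamma, 6), round(delta, 6))
        cps[state] = (cp.Q, cp.theta, cp.phi2)
        print(
            f"{state}: CP(Q={cp.Q}, theta={cp.theta}, phi2={cp.phi2}) "
            f"-> gamma={gamma:+.3f}, delta={delta:+.3f}"
        )

    out = Path(__file__).resolve().parents[1] / "src" / "gagconf" / "_pucker_refs.py"
    lines = [HEADER.format(q=DEFAULT_Q)]
    lines.append("REFERENCE_GAMMA_DELTA: dict[str, tuple[float, float]] = {")
    for state, (g, d) in refs.items():
        lines.append(f'    "{state}": ({g}, {d}),')
    lines.append("}")
    lines.append("")
    lines.append("CANONICAL_CP: dict[str, tuple[float, float, float]] = {")
    for state, (q, t, p) in cps.items():
        lines.append(f'    "{state}": ({q}, {t}, {p}),')
    lines.append("}")
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
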