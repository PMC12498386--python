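"""Frozen pucker reference angles (degrees), derived geometrically.

Generated by scripts/derive_pucker_references.py — do not edit by hand.
Each reference is the (γ, δ) = (C1-C2-C3-C4, C1-O5-C5-C4) dihedral pair of
an idealized ring built at the canonical Cremer-Pople coordinates below
(Q = 0.57 Å). CANONICAL_CP maps state -> (Q, θ, φ2).
"""

REFERENCE_GAMMA_DELTA: dict[str, tuple[float, float]] = {
    "4C1": (-54.554967, 59.715471),
    "1C4": (54.554967, -59.715471),
    "2SO": (-47.676738, -53.614709),
    "1S3": (-23.007529, -27.725034),
}

CANONICAL_CP: dict[str, tuple[float, float, float]] = {
    "4C1": (0.57, 0.0, 0.0),
    "1C4": (0.57, 180.0, 0.0),
    "2SO": (0.57, 90.0, 150),
    "1S3": (0.57, 90.0, 210),
}
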