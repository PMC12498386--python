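# Rigid explicit water model registry: site geometry in the molecular frame
# (Å; oxygen at the origin, H-O-H bisector along +z, hydrogens in the xz
# plane) plus point charges (e) and the single oxygen-oxygen Lennard-Jones
# parameters. Geometries and charges follow each model's original
# publication; dipole_reference is the gas-phase dipole (D) implied by the
# fixed charges.
tip3p:
  r_oh: 0.9572
  hoh_angle: 104.52
  charges: {O: -0.834, H: 0.417}
  lj_sigma: 3.15061
  lj_epsilon: 0.1521
  dipole_reference: 2.35
tip4p:
  r_oh: 0.9572
  hoh_angle: 104.52
  m_site: 0.15       # massless charge site on the bisector, towards H
  charges: {O: 0.0, H: 0.52, M: -1.04}
  lj_sigma: 3.15365
  lj_epsilon: 0.1550
  dipole_reference: 2.18
tip5p:
  r_oh: 0.9572
  hoh_angle: 104.52
  lone_pairs: {r_ol: 0.70, lol_angle: 109.47}
  charges: {O: 0.0, H: 0.241, L: -0.241}
  lj_sigma: 3.12
  lj_epsilon: 0.16
  dipole_reference: 2.29
spce:
  r_oh: 1.0
  hoh_angle: 109.47
  charges: {O: -0.8476, H: 0.4238}
  lj_sigma: 3.166
  lj_epsilon: 0.1553
  dipole_reference: 2.35
opc:
  r_oh: 0.8724
  hoh_angle: 103.6
  m_site: 0.1594
  charges: {O: 0.0, H: 0.6791, M: -1.3582}
  lj_sigma: 3.16655
  lj_epsilon: 0.2128
  dipole_reference: 2.48
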