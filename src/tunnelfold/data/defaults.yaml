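# Default physical tables for tunnelfold.
#
# sidechain_radius: radius (Å) of the single pseudo-atom standing in for the
# side chain, derived from residue volume minus a common backbone volume
# (sphere of equal volume).  mass: average residue mass (Da).
residues:
  A: {hydrophobic: true,  sidechain_radius: 1.90, mass: 71.08}
  C: {hydrophobic: true,  sidechain_radius: 2.26, mass: 103.14}
  D: {hydrophobic: false, sidechain_radius: 2.30, mass: 115.09}
  E: {hydrophobic: false, sidechain_radius: 2.65, mass: 129.12}
  F: {hydrophobic: true,  sidechain_radius: 3.14, mass: 147.18}
  G: {hydrophobic: false, sidechain_radius: 1.35, mass: 57.05}
  H: {hydrophobic: false, sidechain_radius: 2.81, mass: 137.14}
  I: {hydrophobic: true,  sidechain_radius: 2.94, mass: 113.16}
  K: {hydrophobic: false, sidechain_radius: 2.96, mass: 128.17}
  L: {hydrophobic: true,  sidechain_radius: 2.94, mass: 113.16}
  M: {hydrophobic: true,  sidechain_radius: 2.90, mass: 131.19}
  N: {hydrophobic: false, sidechain_radius: 2.34, mass: 114.10}
  P: {hydrophobic: false, sidechain_radius: 2.32, mass: 97.12}
  Q: {hydrophobic: false, sidechain_radius: 2.72, mass: 128.13}
  R: {hydrophobic: false, sidechain_radius: 3.00, mass: 156.19}
  S: {hydrophobic: false, sidechain_radius: 1.91, mass: 87.08}
  T: {hydrophobic: false, sidechain_radius: 2.36, mass: 101.10}
  V: {hydrophobic: true,  sidechain_radius: 2.67, mass: 99.13}
  W: {hydrophobic: true,  sidechain_radius: 3.43, mass: 186.21}
  Y: {hydrophobic: false, sidechain_radius: 3.18, mass: 163.18}

# van-der-Waals-style radii (Å) for backbone atom roles.
atom_radii:
  N: 1.55
  CA: 1.70
  C: 1.70
  O: 1.52
  default: 1.70

backbone_geometry:
  bond_lengths:       # Å
    N_CA: 1.458
    CA_C: 1.525
    C_N: 1.329
    C_O: 1.231
  bond_angles:        # degrees
    N_CA_C: 111.0
    CA_C_N: 116.6
    C_N_CA: 121.9
    CA_C_O: 120.5
  dihedrals:          # degrees, per conformational state
    helical:  {phi: -57.0, psi: -47.0, omega: 180.0}
    extended: {phi: -130.0, psi: 135.0, omega: 180.0}
  cb_offset: 2.0      # Å, pseudo side-chain centre distance from CA

hydrophobic_set: [A, C, F, I, L, M, V, W]

tunnel:
  length: 100.0          # Å
  d_max: 20.0            # Å, diameter at both ends
  d_min: 10.0            # Å, diameter at the constriction
  constriction_at: 30.0  # Å from the P-site end
  wall_spacing: 2.8      # Å, target spacing between wall pseudo-atoms
  wall_radius: 1.7       # Å
  wall_jitter: 0.25      # Å
  hydrophobic_fraction: 0.3

energy:
  burial_coefficient: 0.015   # kcal/mol/Å², free energy per buried area

glycosylation:
  per_glycan_shift_kda: 2.5
  d_critical: 67
  d_full: 73
  rise_extended: 3.4   # Å per residue
  rise_helical: 1.5    # Å per residue
  membrane_core: 30.0  # Å
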