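"""Documented analysis presets for the E2–SUMO conjugation study system.

These are the simulation-specific parameters used when analysing the
Ubc9 (E2), SUMO and RanBP2 (E3 fragment) trajectories; they are shipped as
a documented preset rather than hard-wired, because every one of them is a
property of a particular set of simulations, not of the statistics.
"""

# Equilibration period to exclude, per simulated system (ns)
EQUILIBRATION_NS = {
    "ubc9": 2.5,
    "sumo": 5.0,
    "ubc9_sumo": 0.5,
    "ubc9_sumo_ranbp2": 0.4,
}

# SUMO's flexible N-terminal tail (author residue numbers), excluded from
# alignment and fluctuation statistics
SUMO_TAIL_RESIDUES = (-1, 19)

# Time-delay grid for bond-vector autocorrelations (ns); the largest delay
# is chosen slightly longer than half the simulation length
AUTOCORRELATION_DELAYS_NS = (0.0, 0.4, 1.0, 5.0, 30.0)

# Clustering radius (RMSD to centroid, Å): radii tried on the complexes,
# and the values adopted per system
CLUSTER_RADII_TESTED = (2.0, 1.7, 1.5)
CLUSTER_RADIUS = {
    "ubc9_sumo": 1.7,
    "ubc9_sumo_ranbp2": 2.0,
    "joined_ubc9": 1.7,
}

# Initial span trimmed from each trajectory before joining ensembles (ns)
JOINED_ENSEMBLE_TRIM_NS = 10.0

# Functional residue ranges on Ubc9 (author numbering) used for windowed
# correlation-map block contrasts
UBC9_CATALYTIC_SITE = (83, 89)       # His83-Ser89
UBC9_SUMO_MOTIF_BINDING = (121, 131)  # Asn121-Ala131
UBC9_TARGET_RECOGNITION = (132, 141)  # Glu132-Arg141
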