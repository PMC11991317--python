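"""Default electrode-to-grid mappings for the international 10-20 system.

Both default layouts place electrodes on a 9x9 grid whose rows run from the
forehead (row 0) to the occiput (row 8) and whose columns run left (0) to
right (8), preserving the topological neighbour relations of the 10-20
arrangement. The mappings are plain dictionaries and can be overridden by the
user (see `preprocessing.ElectrodeLayout.from_json`).
"""

# DEAP preprocessed channel order (32 EEG channels).
DEAP_EEG_CHANNELS = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7", "CP5", "CP1",
    "P3", "P7", "PO3", "O1", "Oz", "Pz", "Fp2", "AF4", "Fz", "F4",
    "F8", "FC6", "FC2", "Cz", "C4", "T8", "CP6", "CP2", "P4", "P8",
    "PO4", "O2",
)

# Emotiv EPOC channel order used by DREAMER (14 EEG channels).
DREAMER_EEG_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

# name -> (row, col) on the 9x9 grid
GRID_10_20 = {
    "Fp1": (0, 3), "Fp2": (0, 5),
    "AF3": (1, 3), "AF4": (1, 5),
    "F7": (2, 0), "F3": (2, 2), "Fz": (2, 4), "F4": (2, 6), "F8": (2, 8),
    "FC5": (3, 1), "FC1": (3, 3), "FC2": (3, 5), "FC6": (3, 7),
    "T7": (4, 0), "C3": (4, 2), "Cz": (4, 4), "C4": (4, 6), "T8": (4, 8),
    "CP5": (5, 1), "CP1": (5, 3), "CP2": (5, 5), "CP6": (5, 7),
    "P7": (6, 0), "P3": (6, 2), "Pz": (6, 4), "P4": (6, 6), "P8": (6, 8),
    "PO3": (7, 3), "PO4": (7, 5),
    "O1": (8, 3), "Oz": (8, 4), "O2": (8, 5),
}

DEAP_PLACEMENT = {ch: GRID_10_20[ch] for ch in DEAP_EEG_CHANNELS}
DREAMER_PLACEMENT = {ch: GRID_10_20[ch] for ch in DREAMER_EEG_CHANNELS}
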