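"""Residue alphabets, pair orderings and physicochemical partitions.

Every window-level feature works over a small categorical alphabet: the 20
standard amino acids plus the pseudo-residue ``X`` (chain-end padding and
non-standard letters), a 3-state secondary structure, a 2-state solvent
accessibility, and two physicochemical partitions (hydropathy, charge).
``X`` is always its own category, which fixes the category counts used by
the pseudocount formulas (q = 21, 4, 3, 7, 4).
"""

from __future__ import annotations

# 20 standard amino acids in one-letter alphabetical order. This is also the
# row/column order of the 20x20 ordered-pair matrix (AA, AC, AD, ..., YY).
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: pseudo-residue used for chain-end padding and for non-standard letters
X = "X"

AA21 = AA20 + X

#: letters that occur in real sequence data but are mapped to X
NONSTANDARD = set("BJOUZ")

#: the 400 ordered amino-acid pairs, row-major over AA20 (J-order)
PAIRS400 = tuple(a + b for a in AA20 for b in AA20)
PAIR_INDEX = {p: i for i, p in enumerate(PAIRS400)}

# secondary structure: helix / sheet / coil, plus padding
SS3 = "HEC"
SS4 = SS3 + X

# relative solvent accessibility classes: exposed / buried, plus padding
RSA_EXPOSED = "e"
RSA_BURIED = "b"
RSA2 = RSA_EXPOSED + RSA_BURIED
RSA3 = RSA2 + X

#: RSA value strictly above this is "exposed"
RSA_THRESHOLD = 0.25

# Hydropathy partition: six bins of the Kyte-Doolittle scale, from most
# hydrophobic to most hydrophilic. With X this gives q = 7 categories.
HYDROPATHY_CLASSES: dict[str, str] = {
    "h1": "IVL",     # strongly hydrophobic (KD >= 3.8)
    "h2": "FCMA",    # hydrophobic (1.8 .. 2.8)
    "h3": "GTSW",    # weakly amphipathic (-0.9 .. -0.4)
    "h4": "YP",      # weakly hydrophilic (-1.6 .. -1.3)
    "h5": "HEQDN",   # hydrophilic (-3.5 .. -3.2)
    "h6": "KR",      # strongly hydrophilic (<= -3.9)
}

# Charge partition after side-chain ionisation: q = 4 with X.
CHARGE_CLASSES: dict[str, str] = {
    "positive": "HKR",
    "negative": "DE",
    "neutral": "ACFGILMNPQSTVWY",
}

# Background amino-acid frequencies (Robinson & Robinson composition),
# used by the synthetic generator; renormalised over AA20 order.
BACKGROUND_AA_FREQ: dict[str, float] = {
    "A": 0.078, "C": 0.019, "D": 0.054, "E": 0.063, "F": 0.039,
    "G": 0.074, "H": 0.022, "I": 0.051, "K": 0.057, "L": 0.090,
    "M": 0.022, "N": 0.045, "P": 0.052, "Q": 0.043, "R": 0.051,
    "S": 0.071, "T": 0.058, "V": 0.064, "W": 0.013, "Y": 0.032,
}


def class_map(partition: dict[str, str], include_x: bool = True) -> dict[str, str]:
    """Invert a partition {class -> letters} into {letter -> class}.

    Raises if the partition does not cover AA20 exactly once. With
    ``include_x`` the pseudo-residue maps to its own class ``"X"``.
    """
    mapping: dict[str, str] = {}
    for name, letters in partition.items():
        for aa in letters:
            if aa in mapping:
                raise ValueError(f"residue {aa!r} assigned to two classes")
            mapping[aa] = name
    missing = set(AA20) - set(mapping)
    if missing:
        raise ValueError(f"partition does not cover residues: {sorted(missing)}")
    if include_x:
        mapping[X] = X
    return mapping


def partition_categories(partition: dict[str, str]) -> list[str]:
    """Ordered category names of a partition, with X appended last."""
    return list(partition) + [X]
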