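"""Per-fragment feature blocks and their per-ligand fitted artifacts.

The feature vector of one window of length L has seven named blocks:

1. amino acid: 21-dim composition + 2L-dim dual-PWM conservation scores
2. secondary structure: 4-dim composition + 2L-dim dual-PWM scores
3. solvent accessibility: 3-dim composition + 2L-dim dual-PWM scores
4. hydropathy entropy (1)
5. charge entropy (1)
6. correlation group features (10 per selected gap order)
7. binding/non-binding propensity factors of the central residue (2)

Total dimension: 30 + 6L + 10*(number of selected orders) + 2.

Dual PWMs are position weight matrices fitted separately on positive and
negative training fragments: m[i][j] = ln(p[i][j] / p0[j]) with square-root
pseudocounts p = (n + sqrt(N)/q) / (N + sqrt(N)) and a uniform background
p0 = 1/q. The same pseudocount smooths the category probabilities inside
the Shannon entropies of blocks 4-5. The propensity factor of amino acid i
for class j (binding / non-binding) is F_ij = (n_ij / N_i) / (N_j / N_t):
the class share among occurrences of residue i relative to the class share
overall; F > 1 marks residues over-represented among binders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabets import (
    AA20,
    AA21,
    CHARGE_CLASSES,
    HYDROPATHY_CLASSES,
    RSA3,
    SS4,
    X,
    class_map,
)
from .correlation import (
    PairScreen,
    correlation_features,
    correlation_table,
    pair_frequencies,
    screen_pairs,
    select_orders,
)
from .io import AnnotatedChain, Fragment

__all__ = [
    "PropensityTable",
    "PWMModel",
    "LigandProfile",
    "FEATURE_MASKS",
    "fit_propensity",
    "fit_propensity_from_fragments",
    "propensity_features",
    "composition",
    "fit_pwm",
    "pwm_features",
    "entropy_feature",
    "fit_profile",
    "assemble",
    "feature_names",
]

#: ablation masks -> feature blocks included
FEATURE_MASKS: dict[str, tuple[int, ...]] = {
    "a": (1, 2, 3, 4, 5),
    "b": (1, 2, 3, 4, 5, 6),
    "c": (1, 2, 3, 4, 5, 7),
    "d": (1, 2, 3, 4, 5, 6, 7),
}


# ---------------------------------------------------------------------------
# propensity factors


@dataclass(frozen=True)
class PropensityTable:
    """Binding / non-binding propensity factors over the 20 amino acids.

    F[i][j] = (n_ij / N_i) / (N_j / N_t) with residue-level counts; columns
    j are (binding, non_binding). Satisfies the weighted-mean identity
    sum_i (N_i / N_t) * F[i][j] = 1 for each class j.
    """

    factors: pd.DataFrame  # index AA20, columns ["binding", "non_binding"]
    counts: pd.DataFrame = field(repr=False)  # n_ij; same shape
    n_class: tuple = (0, 0)  # (N_binding, N_non_binding)

    @property
    def n_total(self) -> int:
        return int(sum(self.n_class))

    def factor(self, aa: str, binding: bool) -> float:
        if aa not in AA20:
            return 0.0
        return float(self.factors.loc[aa, "binding" if binding else "non_binding"])


def _residue_class_counts(residues: Iterable[tuple[str, bool]]) -> pd.DataFrame:
    binding: dict[str, int] = {}
    non_binding: dict[str, int] = {}
    for aa, is_binding in residues:
        if aa not in AA20:  # X carries no identity information
            continue
        bucket = binding if is_binding else non_binding
        bucket[aa] = bucket.get(aa, 0) + 1
    return pd.DataFrame(
        {
            "binding": [binding.get(aa, 0) for aa in AA20],
            "non_binding": [non_binding.get(aa, 0) for aa in AA20],
        },
        index=list(AA20),
        dtype=np.int64,
    )


def _propensity_from_counts(counts: pd.DataFrame) -> PropensityTable:
    n_j = counts.sum(axis=0)  # class totals
    n_i = counts.sum(axis=1)  # per-residue totals
    n_t = int(n_i.sum())
    if (n_j == 0).any():
        raise ValueError("training set needs at least one residue of each class")
    factors = pd.DataFrame(0.0, index=counts.index, columns=counts.columns)
    for aa in counts.index:
        if n_i[aa] == 0:
            warnings.warn(f"residue {aa} absent from training set; propensity set to 0")
            continue
        for cls in counts.columns:
            factors.loc[aa, cls] = (counts.loc[aa, cls] / n_i[aa]) / (n_j[cls] / n_t)
    return PropensityTable(
        factors=factors,
        counts=counts,
        n_class=(int(n_j["binding"]), int(n_j["non_binding"])),
    )


def fit_propensity(chains: Iterable[AnnotatedChain]) -> PropensityTable:
    """Fit propensity factors from residue-level counts over whole chains."""
    residues = (
        (aa, (i + 1) in chain.binding_positions)
        for chain in chains
        for i, aa in enumerate(chain.sequence)
    )
    return _propensity_from_counts(_residue_class_counts(residues))


def fit_propensity_from_fragments(fragments: Iterable[Fragment]) -> PropensityTable:
    """Fit propensity factors from the central residues of training fragments.

    Inside cross-validation the training material is a set of fragments;
    their centres are exactly the training residues.
    """
    residues = ((f.center, f.label) for f in fragments)
    return _propensity_from_counts(_residue_class_counts(residues))


def propensity_features(fragment: Fragment, table: PropensityTable) -> np.ndarray:
    """(F_binding, F_non_binding) of the central residue (0, 0 for X)."""
    aa = fragment.center
    return np.array([table.factor(aa, True), table.factor(aa, False)])


# ---------------------------------------------------------------------------
# composition, PWMs, entropies


def composition(window: str, alphabet: str) -> np.ndarray:
    """Per-symbol frequency of a window over an alphabet; sums to 1."""
    if not window:
        raise ValueError("empty window")
    vec = np.zeros(len(alphabet))
    index = {sym: i for i, sym in enumerate(alphabet)}
    for sym in window:
        vec[index[sym]] += 1
    return vec / len(window)


def _sqrt_pseudocount_probs(counts: np.ndarray, n: float, q: int) -> np.ndarray:
    """p_j = (n_j + sqrt(N)/q) / (N + sqrt(N)); sums to 1 when sum(n_j) = N."""
    root = np.sqrt(n)
    return (counts + root / q) / (n + root)


@dataclass(frozen=True)
class PWMModel:
    """Dual position weight matrices over one window alphabet.

    ``m_pos``/``m_neg`` are L x q log-odds score matrices ln(p/p0) fitted on
    positive and negative training fragments with square-root pseudocounts
    and uniform background p0 = 1/q.
    """

    alphabet: str
    m_pos: np.ndarray
    m_neg: np.ndarray
    p_pos: np.ndarray = field(repr=False)
    p_neg: np.ndarray = field(repr=False)

    @property
    def L(self) -> int:
        return self.m_pos.shape[0]

    @property
    def q(self) -> int:
        return len(self.alphabet)


def _pwm_half(windows: Sequence[str], alphabet: str) -> tuple[np.ndarray, np.ndarray]:
    if not windows:
        raise ValueError("cannot fit a PWM on an empty training set")
    L = len(windows[0])
    q = len(alphabet)
    index = {sym: i for i, sym in enumerate(alphabet)}
    counts = np.zeros((L, q))
    for w in windows:
        if len(w) != L:
            raise ValueError("all training windows must share one length")
        for i, sym in enumerate(w):
            counts[i, index[sym]] += 1
    n = len(windows)
    probs = _sqrt_pseudocount_probs(counts, n, q)
    scores = np.log(probs * q)  # ln(p / (1/q))
    return probs, scores


def fit_pwm(
    pos_windows: Sequence[str], neg_windows: Sequence[str], alphabet: str
) -> PWMModel:
    """Fit the positive and negative score matrices on training windows."""
    p_pos, m_pos = _pwm_half(pos_windows, alphabet)
    p_neg, m_neg = _pwm_half(neg_windows, alphabet)
    if m_pos.shape != m_neg.shape:
        raise ValueError("positive and negative windows must share one length")
    return PWMModel(alphabet=alphabet, m_pos=m_pos, m_neg=m_neg, p_pos=p_pos, p_neg=p_neg)


def pwm_features(window: str, model: PWMModel) -> np.ndarray:
    """2L scores: per-position positive-matrix scores then negative-matrix."""
    if len(window) != model.L:
        raise ValueError("window length does not match fitted PWM")
    index = {sym: i for i, sym in enumerate(model.alphabet)}
    idx = [index[sym] for sym in window]
    pos = model.m_pos[np.arange(model.L), idx]
    neg = model.m_neg[np.arange(model.L), idx]
    return np.concatenate([pos, neg])


def entropy_feature(window: str, classification: Mapping[str, str], q: int) -> float:
    """Shannon entropy (bits) of a physicochemical classification of a window.

    Category probabilities use the same square-root pseudocount as the PWMs,
    so empty categories keep a small positive mass; with counts uniform over
    all q categories the entropy attains its maximum log2(q) exactly.
    """
    cats: dict[str, int] = {}
    for sym in window:
        cats[classification[sym]] = cats.get(classification[sym], 0) + 1
    if len(cats) > q:
        raise ValueError("classification has more categories than q")
    n = len(window)
    counts = np.zeros(q)
    counts[: len(cats)] = sorted(cats.values())  # entropy is label-invariant
    p = _sqrt_pseudocount_probs(counts, n, q)
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# the per-ligand profile and feature assembly


@dataclass(frozen=True)
class LigandProfile:
    """All fitted artifacts needed to featurise fragments for one ligand."""

    ligand: str
    L: int
    orders: tuple
    screens: tuple  # one PairScreen per order, ascending
    propensity: PropensityTable
    pwm_aa: PWMModel
    pwm_ss: PWMModel
    pwm_rsa: PWMModel
    hydropathy: Mapping[str, str] = field(default_factory=lambda: dict(HYDROPATHY_CLASSES))
    charge: Mapping[str, str] = field(default_factory=lambda: dict(CHARGE_CLASSES))

    @property
    def q_hydropathy(self) -> int:
        return len(self.hydropathy) + 1  # + X

    @property
    def q_charge(self) -> int:
        return len(self.charge) + 1

    @property
    def n_features(self) -> int:
        return 30 + 6 * self.L + 10 * len(self.orders) + 2


def fit_profile(
    fragments: Sequence[Fragment],
    orders: Sequence[int],
    ligand: str = "ION",
    hydropathy: Mapping[str, str] | None = None,
    charge: Mapping[str, str] | None = None,
) -> LigandProfile:
    """Fit screens, propensity table and the three dual PWMs on training fragments."""
    if not fragments:
        raise ValueError("empty training set")
    L = fragments[0].L
    pos = [f for f in fragments if f.label]
    neg = [f for f in fragments if not f.label]
    if not pos or not neg:
        raise ValueError("training set needs both positive and negative fragments")
    screens = tuple(
        screen_pairs(pair_frequencies(pos, d), pair_frequencies(neg, d), order=d)
        for d in sorted(orders)
    )
    return LigandProfile(
        ligand=ligand,
        L=L,
        orders=tuple(sorted(orders)),
        screens=screens,
        propensity=fit_propensity_from_fragments(fragments),
        pwm_aa=fit_pwm([f.residues for f in pos], [f.residues for f in neg], AA21),
        pwm_ss=fit_pwm([f.ss_window for f in pos], [f.ss_window for f in neg], SS4),
        pwm_rsa=fit_pwm([f.rsa_window for f in pos], [f.rsa_window for f in neg], RSA3),
        hydropathy=dict(hydropathy or HYDROPATHY_CLASSES),
        charge=dict(charge or CHARGE_CLASSES),
    )


def select_profile_orders(chains: Iterable[AnnotatedChain], threshold: float = 0.10) -> list[int]:
    """Ligand-level gap-order selection from a chain set."""
    return select_orders(correlation_table(chains), threshold)


def assemble(
    fragment: Fragment, profile: LigandProfile, mask: str = "d"
) -> np.ndarray:
    """Concatenate the masked feature blocks of one fragment.

    Masks: "a" = blocks 1-5, "b" = +correlation, "c" = +propensity,
    "d" = all seven blocks.
    """
    blocks = FEATURE_MASKS[mask]
    hyd = class_map(dict(profile.hydropathy))
    chg = class_map(dict(profile.charge))
    parts: list[np.ndarray] = []
    if 1 in blocks:
        parts.append(composition(fragment.residues, AA21))
        parts.append(pwm_features(fragment.residues, profile.pwm_aa))
    if 2 in blocks:
        parts.append(composition(fragment.ss_window, SS4))
        parts.append(pwm_features(fragment.ss_window, profile.pwm_ss))
    if 3 in blocks:
        parts.append(composition(fragment.rsa_window, RSA3))
        parts.append(pwm_features(fragment.rsa_window, profile.pwm_rsa))
    if 4 in blocks:
        parts.append(
            np.array([entropy_feature(fragment.residues, hyd, profile.q_hydropathy)])
        )
    if 5 in blocks:
        parts.append(np.array([entropy_feature(fragment.residues, chg, profile.q_charge)]))
    if 6 in blocks:
        parts.append(correlation_features(fragment, profile.screens))
    if 7 in blocks:
        parts.append(propensity_features(fragment, profile.propensity))
    return np.concatenate(parts)


def feature_names(profile: LigandProfile, mask: str = "d") -> list[str]:
    """Column names matching ``assemble``, prefixed by block."""
    blocks = FEATURE_MASKS[mask]
    L = profile.L
    names: list[str] = []
    if 1 in blocks:
        names += [f"aa_comp_{sym}" for sym in AA21]
        names += [f"aa_pwm_pos_{i:02d}" for i in range(1, L + 1)]
        names += [f"aa_pwm_neg_{i:02d}" for i in range(1, L + 1)]
    if 2 in blocks:
        names += [f"ss_comp_{sym}" for sym in SS4]
        names += [f"ss_pwm_pos_{i:02d}" for i in range(1, L + 1)]
        names += [f"ss_pwm_neg_{i:02d}" for i in range(1, L + 1)]
    if 3 in blocks:
        names += [f"rsa_comp_{sym}" for sym in RSA3]
        names += [f"rsa_pwm_pos_{i:02d}" for i in range(1, L + 1)]
        names += [f"rsa_pwm_neg_{i:02d}" for i in range(1, L + 1)]
    if 4 in blocks:
        names += ["hydropathy_entropy"]
    if 5 in blocks:
        names += ["charge_entropy"]
    if 6 in blocks:
        for d in profile.orders:
            names += [f"corr_d{d}_g{g + 1:02d}" for g in range(10)]
    if 7 in blocks:
        names += ["propensity_binding", "propensity_non_binding"]
    return names


def feature_matrix(
    fragments: Sequence[Fragment], profile: LigandProfile, mask: str = "d"
) -> np.ndarray:
    """Stack ``assemble`` over fragments into an (n, p) design matrix."""
    return np.vstack([assemble(f, profile, mask) for f in fragments])
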