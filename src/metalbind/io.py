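"""Chain and annotation I/O, and sliding-window fragment construction.

File dialects
-------------
* sequences: plain FASTA, one record per protein chain;
* binding annotations: 3-column TSV ``chain_id  ligand_id  positions`` where
  positions are comma-separated 1-based sequence indices (a minimal dialect
  of BioLip-style annotation tables);
* per-residue structure annotations: 4-column TSV
  ``chain_id  position  ss  rsa`` with ss in {H,E,C} and rsa a real in [0,1].

Positions are 1-based sequence indices throughout (not author numbering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabets import AA20, NONSTANDARD, RSA_THRESHOLD, SS3, X

__all__ = [
    "AnnotatedChain",
    "Fragment",
    "read_chains",
    "rsa_to_classes",
    "make_fragments",
    "fragments_to_frame",
    "frame_to_fragments",
    "write_chains",
]


def clean_sequence(seq: str, chain_id: str = "?") -> str:
    """Uppercase a sequence and map non-standard letters to X (with warning)."""
    seq = seq.upper()
    cleaned = []
    for i, aa in enumerate(seq, start=1):
        if aa in AA20 or aa == X:
            cleaned.append(aa)
        elif aa in NONSTANDARD or aa.isalpha():
            warnings.warn(
                f"chain {chain_id}: non-standard residue {aa!r} at position {i} mapped to X"
            )
            cleaned.append(X)
        else:
            raise ValueError(f"chain {chain_id}: invalid sequence character {aa!r}")
    return "".join(cleaned)


@dataclass(frozen=True)
class AnnotatedChain:
    """A protein chain with binding-residue and structural annotations.

    Parameters
    ----------
    chain_id : str
    sequence : str
        Over the 20-letter alphabet plus X (non-standard residues).
    binding_positions : frozenset of int
        1-based positions of residues annotated as binding the metal ion.
    ss : str, optional
        Per-residue 3-class secondary structure over {H, E, C}.
    rsa : tuple of float, optional
        Per-residue relative solvent accessibility in [0, 1].
    """

    chain_id: str
    sequence: str
    binding_positions: frozenset = field(default_factory=frozenset)
    ss: str | None = None
    rsa: tuple | None = None

    def __post_init__(self):
        n = len(self.sequence)
        if n < 1:
            raise ValueError(f"chain {self.chain_id}: empty sequence")
        object.__setattr__(self, "binding_positions", frozenset(int(p) for p in self.binding_positions))
        bad = [p for p in self.binding_positions if not 1 <= p <= n]
        if bad:
            raise ValueError(
                f"chain {self.chain_id}: binding position(s) {sorted(bad)} outside [1, {n}]"
            )
        if self.ss is not None:
            if len(self.ss) != n:
                raise ValueError(f"chain {self.chain_id}: ss length != sequence length")
            if any(c not in SS3 + X for c in self.ss):
                raise ValueError(f"chain {self.chain_id}: invalid ss symbol")
        if self.rsa is not None:
            rsa = tuple(float(v) for v in self.rsa)
            if len(rsa) != n:
                raise ValueError(f"chain {self.chain_id}: rsa length != sequence length")
            if any(not 0.0 <= v <= 1.0 for v in rsa):
                raise ValueError(f"chain {self.chain_id}: rsa values must lie in [0, 1]")
            object.__setattr__(self, "rsa", rsa)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def labels(self) -> np.ndarray:
        """Boolean array, True at binding positions (0-based indexing)."""
        lab = np.zeros(len(self.sequence), dtype=bool)
        for p in self.binding_positions:
            lab[p - 1] = True
        return lab

    def rsa_classes(self) -> str | None:
        """Dichotomised RSA string over {e, b}, or None if RSA is absent."""
        if self.rsa is None:
            return None
        return rsa_to_classes(self.rsa)


@dataclass(frozen=True)
class Fragment:
    """A length-L window centred on one residue, padded with X at chain ends."""

    chain_id: str
    center_position: int  # 1-based position of the central residue
    residues: str
    ss_window: str
    rsa_window: str
    label: bool

    def __post_init__(self):
        L = len(self.residues)
        if L % 2 != 1 or L < 3:
            raise ValueError("window length must be odd and >= 3")
        if len(self.ss_window) != L or len(self.rsa_window) != L:
            raise ValueError("ss/rsa windows must match window length")

    @property
    def L(self) -> int:
        return len(self.residues)

    @property
    def center(self) -> str:
        return self.residues[(self.L - 1) // 2]


def rsa_to_classes(rsa_values: Sequence[float]) -> str:
    """Dichotomise RSA values: strictly above 0.25 -> exposed 'e', else buried 'b'."""
    out = []
    for v in rsa_values:
        v = float(v)
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"RSA value {v} outside [0, 1]")
        out.append("e" if v > RSA_THRESHOLD else "b")
    return "".join(out)


def _read_annotations(path) -> dict[str, dict[str, list[int]]]:
    """Parse the 3-column binding TSV into {chain_id: {ligand: [positions]}}."""
    table: dict[str, dict[str, list[int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated columns")
            chain_id, ligand, pos_str = parts
            positions = [int(p) for p in pos_str.split(",") if p.strip()]
            table.setdefault(chain_id, {}).setdefault(ligand, []).extend(positions)
    return table


def _read_structure(path) -> dict[str, dict[int, tuple[str, float]]]:
    """Parse the per-residue structure TSV into {chain: {pos: (ss, rsa)}}."""
    table: dict[str, dict[int, tuple[str, float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chain_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 tab-separated columns")
            chain_id, pos, ss, rsa = parts
            table.setdefault(chain_id, {})[int(pos)] = (ss, float(rsa))
    return table


def read_chains(
    fasta_path,
    annotation_path=None,
    structure_path=None,
    ligand: str | None = None,
) -> list[AnnotatedChain]:
    """Read chains from FASTA plus optional binding/structure annotations.

    Chains without an annotation row get an empty binding set. When
    ``ligand`` is given, only rows for that ligand are used; otherwise the
    union over all ligands annotated on the chain is taken. A chain whose
    annotation contains an out-of-range position is rejected with a warning
    naming the chain and position.
    """
    annotations = _read_annotations(annotation_path) if annotation_path else {}
    structure = _read_structure(structure_path) if structure_path else {}

    chains: list[AnnotatedChain] = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        chain_id = record.id
        seq = clean_sequence(str(record.seq), chain_id)
        rows = annotations.get(chain_id, {})
        if ligand is not None:
            positions = set(rows.get(ligand, []))
        else:
            positions = set().union(*rows.values()) if rows else set()
        bad = [p for p in positions if not 1 <= p <= len(seq)]
        if bad:
            warnings.warn(
                f"chain {chain_id} rejected: binding position(s) {sorted(bad)} "
                f"outside [1, {len(seq)}]"
            )
            continue
        ss = rsa = None
        if chain_id in structure:
            per_res = structure[chain_id]
            if set(per_res) != set(range(1, len(seq) + 1)):
                warnings.warn(f"chain {chain_id}: incomplete structure annotation ignored")
            else:
                ss = "".join(per_res[i][0] for i in range(1, len(seq) + 1))
                rsa = tuple(per_res[i][1] for i in range(1, len(seq) + 1))
        chains.append(
            AnnotatedChain(chain_id, seq, frozenset(positions), ss=ss, rsa=rsa)
        )
    return chains


def write_chains(
    chains: Iterable[AnnotatedChain],
    fasta_path,
    annotation_path=None,
    structure_path=None,
    ligand: str = "ION",
) -> None:
    """Write chains back to the FASTA/TSV dialects ``read_chains`` accepts."""
    chains = list(chains)
    records = [
        SeqRecord(Seq(c.sequence), id=c.chain_id, description="") for c in chains
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if annotation_path is not None:
        with open(annotation_path, "w") as fh:
            for c in chains:
                if c.binding_positions:
                    pos = ",".join(str(p) for p in sorted(c.binding_positions))
                    fh.write(f"{c.chain_id}\t{ligand}\t{pos}\n")
    if structure_path is not None:
        with open(structure_path, "w") as fh:
            for c in chains:
                if c.ss is None or c.rsa is None:
                    continue
                for i, (ss, rsa) in enumerate(zip(c.ss, c.rsa), start=1):
                    fh.write(f"{c.chain_id}\t{i}\t{ss}\t{rsa:.4f}\n")


def make_fragments(chain: AnnotatedChain, L: int) -> list[Fragment]:
    """Cut a chain into len(chain) windows of odd length L, padded with X.

    Window k is centred on residue k; its label is positive iff k is a
    binding position. Padding applies identically to residue, secondary
    structure and RSA windows.
    """
    if L % 2 != 1 or L < 3:
        raise ValueError("window length L must be odd and >= 3")
    half = (L - 1) // 2
    pad = X * half
    seq = pad + chain.sequence + pad
    ss = pad + (chain.ss if chain.ss is not None else X * len(chain)) + pad
    rsa_cls = chain.rsa_classes()
    rsa = pad + (rsa_cls if rsa_cls is not None else X * len(chain)) + pad
    binding = chain.binding_positions
    fragments = []
    for k in range(1, len(chain) + 1):
        i = k - 1  # start of window in padded coordinates
        fragments.append(
            Fragment(
                chain_id=chain.chain_id,
                center_position=k,
                residues=seq[i : i + L],
                ss_window=ss[i : i + L],
                rsa_window=rsa[i : i + L],
                label=k in binding,
            )
        )
    return fragments


def fragments_to_frame(fragments: Iterable[Fragment]) -> pd.DataFrame:
    """Tabulate fragments as a DataFrame (round-trips via frame_to_fragments)."""
    rows = [
        {
            "chain_id": f.chain_id,
            "center_position": f.center_position,
            "residues": f.residues,
            "ss_window": f.ss_window,
            "rsa_window": f.rsa_window,
            "label": int(f.label),
        }
        for f in fragments
    ]
    return pd.DataFrame(rows)


def frame_to_fragments(frame: pd.DataFrame) -> list[Fragment]:
    return [
        Fragment(
            chain_id=str(r.chain_id),
            center_position=int(r.center_position),
            residues=str(r.residues),
            ss_window=str(r.ss_window),
            rsa_window=str(r.rsa_window),
            label=bool(r.label),
        )
        for r in frame.itertuples(index=False)
    ]
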