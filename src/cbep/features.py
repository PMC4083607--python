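"""Per-residue feature construction.

Each residue of an antigen chain is encoded as a 750-dimensional vector
(at the default window size N = 11) made of five named blocks:

====================  =====  ======  =====
block                 cols   window  width
====================  =====  ======  =====
evolutionary          20     N       20·N
secondary             3      N       3·N
disorder              1      N       1·N
physicochemical       6      N       6·N
dipeptide             420    —       420
====================  =====  ======  =====

Windowed blocks concatenate the rows of a per-residue table over a
sliding window of N residues centred on the target; (N−1)/2 zero-valued
pseudoterminal positions pad each chain end so terminal residues have
full windows. Raw PSSM substitution scores are squashed into (0, 1) with
the logistic function 1/(1+e^−x) before windowing. The dipeptide block
(20 amino-acid composition frequencies + 400 ordered dipeptide
frequencies) is a whole-chain quantity replicated on every residue row.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import (
    NONSTANDARD_AA,
    STANDARD_AA,
    AntigenRecord,
    ProfileSet,
)

__all__ = [
    "WindowConfig",
    "PhysicochemicalScales",
    "FeatureMatrix",
    "load_scales",
    "normalize_pssm",
    "window_encode",
    "dipeptide_composition",
    "encode_residues",
    "DIPEPTIDE_DIM",
]

#: 20 AAC components + 400 ordered dipeptides.
DIPEPTIDE_DIM = 420

_BLOCK_COLS = {"evolutionary": 20, "secondary": 3, "disorder": 1, "physicochemical": 6}


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window configuration; ``window_size`` must be odd."""

    window_size: int = 11

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValueError(f"window size must be odd and >= 1, got {self.window_size}")

    @property
    def pad(self) -> int:
        """Pseudoterminal residues added at each chain end: (N − 1) / 2."""
        return (self.window_size - 1) // 2


class PhysicochemicalScales:
    """Six per-amino-acid propensity scales, min-max normalized to [0, 1].

    Non-standard letters (B, Z, X, U, O) map to all-zero values so chain
    indexing stays aligned with the external profile files.
    """

    def __init__(self, table: pd.DataFrame):
        missing = set(STANDARD_AA) - set(table.index)
        if missing:
            raise ValueError(f"scales table missing amino acids {sorted(missing)}")
        if table.shape[1] != 6:
            raise ValueError(f"expected 6 scales, got {table.shape[1]}")
        table = table.loc[list(STANDARD_AA)].astype(float)
        lo, hi = table.min(axis=0), table.max(axis=0)
        self.table = (table - lo) / (hi - lo)
        self.names = list(table.columns)

    def encode(self, sequence: str) -> np.ndarray:
        """Per-residue (L, 6) matrix; unknown residues get zeros."""
        out = np.zeros((len(sequence), 6))
        for i, aa in enumerate(sequence):
            if aa in STANDARD_AA:
                out[i] = self.table.loc[aa].to_numpy()
        return out


def load_scales(path: str | Path | None = None) -> PhysicochemicalScales:
    """Load the physicochemical scales TSV (the packaged default if ``path`` is None)."""
    if path is None:
        ref = resources.files("cbep.data") / "scales.tsv"
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t", comment="#", index_col=0)
    else:
        table = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return PhysicochemicalScales(table)


@dataclass
class FeatureMatrix:
    """Residues × features table with a named block layout."""

    values: np.ndarray
    block_layout: list[tuple[str, int]]  # ordered (name, width)
    feature_names: list[str]

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.block_layout)
        if self.values.shape[1] != total:
            raise ValueError(
                f"feature width {self.values.shape[1]} != layout total {total}"
            )
        if len(self.feature_names) != total:
            raise ValueError("feature_names length != feature width")

    def block(self, name: str) -> np.ndarray:
        """The columns of one named block."""
        start = 0
        for bname, width in self.block_layout:
            if bname == name:
                return self.values[:, start : start + width]
            start += width
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


def normalize_pssm(scores: np.ndarray) -> np.ndarray:
    """Logistic normalization f(x) = 1 / (1 + e^−x) of raw PSSM scores.

    Total function: any finite score maps strictly inside (0, 1); a raw
    score of 0 maps to exactly 0.5.
    """
    return expit(np.asarray(scores, dtype=float))


def window_encode(
    table: np.ndarray, cfg: WindowConfig, pad_value: float = 0.0
) -> np.ndarray:
    """Concatenate each residue's window of N table rows into one feature row.

    ``table`` is (L, C); the result is (L, N·C). Positions beyond either
    chain end (pseudoterminal residues) contribute constant ``pad_value``
    rows. N = 1 is the identity. N larger than 2·L + 1 is legal: windows
    are simply mostly padding.
    """
    table = np.atleast_2d(np.asarray(table, dtype=float))
    L, C = table.shape
    pad = cfg.pad
    padded = np.full((L + 2 * pad, C), float(pad_value))
    padded[pad : pad + L] = table
    windows = np.lib.stride_tricks.sliding_window_view(
        padded, (cfg.window_size, C)
    )[:, 0]
    return windows.reshape(L, cfg.window_size * C)


def dipeptide_composition(sequence: str) -> np.ndarray:
    """Amino-acid + dipeptide composition of a whole chain (420 components).

    Components 1–20 are the frequencies of the 20 standard residues
    (alphabetical order, denominator = count of standard residues);
    components 21–420 are the 400 ordered dipeptide frequencies AA, AC, …,
    YY over all overlapping pairs. Pairs containing a non-standard letter
    are skipped, and the dipeptide denominator is the number of countable
    pairs; with no countable pair the dipeptide part is all zero.
    """
    if len(sequence) == 0:
        raise ValueError("cannot compute composition of an empty sequence")
    sequence = sequence.upper()
    aa_index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    out = np.zeros(DIPEPTIDE_DIM)

    counts = np.zeros(20)
    for aa in sequence:
        if aa in aa_index:
            counts[aa_index[aa]] += 1
    if counts.sum() > 0:
        out[:20] = counts / counts.sum()

    pair_counts = np.zeros((20, 20))
    for a, b in zip(sequence, sequence[1:]):
        if a in aa_index and b in aa_index:
            pair_counts[aa_index[a], aa_index[b]] += 1
    n_pairs = pair_counts.sum()
    if n_pairs > 0:
        out[20:] = pair_counts.ravel() / n_pairs
    return out


def block_layout(cfg: WindowConfig) -> list[tuple[str, int]]:
    """Ordered (block name, width) pairs for window size N."""
    N = cfg.window_size
    return [
        ("evolutionary", 20 * N),
        ("secondary", 3 * N),
        ("disorder", 1 * N),
        ("physicochemical", 6 * N),
        ("dipeptide", DIPEPTIDE_DIM),
    ]


def _feature_names(cfg: WindowConfig) -> list[str]:
    names: list[str] = []
    offsets = range(-cfg.pad, cfg.pad + 1)
    for block, cols in _BLOCK_COLS.items():
        for off in offsets:
            for c in range(cols):
                names.append(f"{block}:{off:+d}:{c}")
    for i in range(DIPEPTIDE_DIM):
        names.append(f"dipeptide:0:{i}")
    return names


def encode_residues(
    record: AntigenRecord,
    profiles: ProfileSet,
    scales: PhysicochemicalScales | None = None,
    cfg: WindowConfig | None = None,
) -> FeatureMatrix:
    """Build the full per-residue feature matrix for one chain.

    Blocks are concatenated in the fixed order evolutionary, secondary,
    disorder, physicochemical, dipeptide; at N = 11 the total width is
    20·11 + 3·11 + 1·11 + 6·11 + 420 = 750. Raises if any profile length
    disagrees with the chain.
    """
    cfg = cfg or WindowConfig()
    scales = scales or load_scales()
    L = len(record)
    for name, prof in (
        ("evolutionary", profiles.pssm),
        ("secondary", profiles.ss2),
        ("disorder", profiles.disorder),
    ):
        if prof is None:
            raise ValueError(f"missing {name} profile for chain {record.id!r}")
        if len(prof) != L:
            raise ValueError(
                f"{name} profile length {len(prof)} != chain length {L} "
                f"for {record.id!r}"
            )

    evo = window_encode(normalize_pssm(profiles.pssm.scores), cfg)
    ss = window_encode(profiles.ss2.probs, cfg)
    diso = window_encode(profiles.disorder.status[:, None].astype(float), cfg)
    phys = window_encode(scales.encode(record.sequence), cfg)
    dipep = np.tile(dipeptide_composition(record.sequence), (L, 1))

    values = np.hstack([evo, ss, diso, phys, dipep])
    return FeatureMatrix(
        values=values, block_layout=block_layout(cfg), feature_names=_feature_names(cfg)
    )
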