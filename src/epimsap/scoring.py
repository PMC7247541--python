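"""Dual-enzyme MSAP scoring.

Methylation-sensitive AFLP runs every sample twice, once with each of the
two isoschizomers (HpaII, MspI) that share the CCGG recognition site but
differ in methylation sensitivity.  Comparing the two presence/absence
profiles of one fragment distinguishes four conditions, which are encoded
here as a three-state "epilocus" split per locus plus an ambiguous state:

========  ========  ====================  ==========
HpaII     MspI      condition             code
========  ========  ====================  ==========
1         1         nonmethylated         ``100``
0         1         internally methylated ``010``
1         0         externally methylated ``001``
0         0         ambiguous             ``000``
========  ========  ====================  ==========

The ambiguous state carries no presence call at any of the three epiloci
(it expands to all zeros) and never forms an analysis category of its own.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Enzyme",
    "EpilocusState",
    "FragmentPanel",
    "EpilocusMatrix",
    "ReproducibilityReport",
    "score_condition",
    "filter_size_range",
    "filter_reproducibility",
    "align_panels",
    "build_epilocus_matrix",
    "panel_types",
    "PANEL_SUFFIXES",
    "PANEL_NAMES",
    "STATE_CODES",
]


class Enzyme(str, enum.Enum):
    """The two isoschizomers of a dual-enzyme MSAP experiment."""

    HPAII = "HpaII"
    MSPI = "MspI"


class EpilocusState(enum.IntEnum):
    """Four-state scoring of one sample at one CCGG locus."""

    AMBIG = 0
    NONMETH = 1
    INTERNAL = 2
    EXTERNAL = 3


#: string codes of the four states, in the classic "nie" column order
STATE_CODES = {
    EpilocusState.NONMETH: "100",
    EpilocusState.INTERNAL: "010",
    EpilocusState.EXTERNAL: "001",
    EpilocusState.AMBIG: "000",
}

#: expansion of each state (row index = state code) into the three
#: binary epilocus subcolumns (nonmethylated, internal, external)
_EXPANSION = np.array(
    [
        [0, 0, 0],  # AMBIG
        [1, 0, 0],  # NONMETH
        [0, 1, 0],  # INTERNAL
        [0, 0, 1],  # EXTERNAL
    ],
    dtype=np.uint8,
)

#: truth table indexed by 2*hpa + msp
_TRUTH = np.array(
    [
        EpilocusState.AMBIG,     # (0, 0)
        EpilocusState.INTERNAL,  # (0, 1)
        EpilocusState.EXTERNAL,  # (1, 0)
        EpilocusState.NONMETH,   # (1, 1)
    ],
    dtype=np.int8,
)

#: inverse map state -> (hpa, msp)
STATE_TO_BITS = {
    EpilocusState.NONMETH: (1, 1),
    EpilocusState.INTERNAL: (0, 1),
    EpilocusState.EXTERNAL: (1, 0),
    EpilocusState.AMBIG: (0, 0),
}

#: subcolumn suffixes of the expanded binary view, in code order
PANEL_SUFFIXES = ("n", "i", "e")

#: human-readable panel names keyed by suffix
PANEL_NAMES = {
    "n": "nonmethylated",
    "i": "internally_methylated",
    "e": "externally_methylated",
}


def _as_binary(arr, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if a.size and not np.isin(a, (0, 1)).all():
        bad = np.unique(a[~np.isin(a, (0, 1))])
        raise ValueError(f"{name} must be binary (0/1); found {bad.tolist()}")
    return a.astype(np.uint8)


@dataclass
class FragmentPanel:
    """Sample x fragment presence/absence matrix for one enzyme.

    Parameters
    ----------
    enzyme :
        Which isoschizomer produced the panel.
    sample_ids :
        Ordered sample identifiers (rows).
    locus_ids :
        Ordered locus identifiers (columns).
    presence :
        ``(n_samples, n_loci)`` array of 0/1 calls.
    fragment_sizes :
        Optional per-locus fragment length in base pairs; required for
        size filtering.
    """

    enzyme: Enzyme
    sample_ids: list
    locus_ids: list
    presence: np.ndarray
    fragment_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.enzyme = Enzyme(self.enzyme)
        self.sample_ids = list(self.sample_ids)
        self.locus_ids = list(self.locus_ids)
        self.presence = _as_binary(self.presence, "presence")
        if self.presence.ndim != 2:
            raise ValueError("presence must be a 2-D sample x locus matrix")
        n, m = self.presence.shape
        if n != len(self.sample_ids) or m != len(self.locus_ids):
            raise ValueError(
                f"presence shape {self.presence.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if self.fragment_sizes is not None:
            sizes = np.asarray(self.fragment_sizes, dtype=float)
            if sizes.shape != (m,):
                raise ValueError("fragment_sizes must have one entry per locus")
            if (sizes <= 0).any():
                raise ValueError("fragment_sizes must be strictly positive")
            self.fragment_sizes = sizes

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def subset_loci(self, idx) -> "FragmentPanel":
        """Return a new panel restricted to the locus indices ``idx``."""
        idx = np.asarray(idx, dtype=int)
        sizes = None if self.fragment_sizes is None else self.fragment_sizes[idx]
        return FragmentPanel(
            enzyme=self.enzyme,
            sample_ids=self.sample_ids,
            locus_ids=[self.locus_ids[i] for i in idx],
            presence=self.presence[:, idx],
            fragment_sizes=sizes,
        )

    # ------------------------------------------------------------------ I/O

    @classmethod
    def read_tsv(cls, path, enzyme: Enzyme, sep: str = "\t") -> "FragmentPanel":
        """Read a panel from delimited text.

        The header row carries locus identifiers, optionally suffixed with
        ``:size_bp``; the first column holds sample identifiers; values
        must be 0/1.
        """
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        locus_ids, sizes = [], []
        any_size = False
        for col in df.columns:
            col = str(col)
            if ":" in col:
                name, _, size = col.rpartition(":")
                try:
                    sizes.append(float(size))
                    locus_ids.append(name)
                    any_size = True
                    continue
                except ValueError:
                    pass
            locus_ids.append(col)
            sizes.append(np.nan)
        fragment_sizes = np.asarray(sizes) if any_size else None
        if fragment_sizes is not None and np.isnan(fragment_sizes).any():
            raise ValueError("either all or no locus headers may carry ':size_bp'")
        return cls(
            enzyme=enzyme,
            sample_ids=[str(s) for s in df.index],
            locus_ids=locus_ids,
            presence=df.to_numpy(),
            fragment_sizes=fragment_sizes,
        )

    def to_tsv(self, path, sep: str = "\t") -> None:
        if self.fragment_sizes is not None:
            cols = [
                f"{lid}:{int(s) if float(s).is_integer() else s}"
                for lid, s in zip(self.locus_ids, self.fragment_sizes)
            ]
        else:
            cols = list(self.locus_ids)
        df = pd.DataFrame(self.presence, index=self.sample_ids, columns=cols)
        df.index.name = "sample_id"
        df.to_csv(path, sep=sep)


@dataclass
class ReproducibilityReport:
    """Outcome of the duplicate-run reproducibility filter."""

    n_loci_in: int
    n_loci_retained: int
    per_locus_mismatches: np.ndarray
    error_rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.n_loci_retained > self.n_loci_in:
            raise ValueError("cannot retain more loci than supplied")


def score_condition(hpa, msp):
    """Score the four-state condition from the two enzyme calls.

    Truth table: ``(1,1) -> NONMETH``, ``(0,1) -> INTERNAL``,
    ``(1,0) -> EXTERNAL``, ``(0,0) -> AMBIG``.  Accepts scalars or
    arrays; arrays are scored element-wise.
    """
    scalar = np.isscalar(hpa) and np.isscalar(msp)
    h = _as_binary(hpa, "hpa")
    m = _as_binary(msp, "msp")
    if h.shape != m.shape:
        raise ValueError("hpa and msp must have identical shape")
    states = _TRUTH[2 * h.astype(np.int8) + m.astype(np.int8)]
    if scalar:
        return EpilocusState(int(states))
    return states


def filter_size_range(
    panel: FragmentPanel, min_bp: int = 100, max_bp: int = 600
) -> FragmentPanel:
    """Retain loci with ``min_bp <= size <= max_bp`` (inclusive both ends)."""
    if min_bp >= max_bp:
        raise ValueError("min_bp must be smaller than max_bp")
    if panel.fragment_sizes is None:
        raise ValueError("panel carries no fragment sizes; cannot size-filter")
    keep = np.flatnonzero(
        (panel.fragment_sizes >= min_bp) & (panel.fragment_sizes <= max_bp)
    )
    if keep.size == 0:
        warnings.warn(
            f"size filter [{min_bp}, {max_bp}] bp retained no loci", UserWarning
        )
    return panel.subset_loci(keep)


def filter_reproducibility(
    panel_rep1: FragmentPanel,
    panel_rep2: FragmentPanel,
    mode: str = "strict",
    max_mismatch_fraction: float = 0.0,
) -> tuple[FragmentPanel, ReproducibilityReport]:
    """Drop loci whose duplicate runs disagree.

    ``strict`` drops any locus with at least one discordant call between
    the two replicates; ``tolerance`` drops loci whose discordant fraction
    exceeds ``max_mismatch_fraction``.  The retained calls are those of
    replicate 1.
    """
    if mode not in ("strict", "tolerance"):
        raise ValueError("mode must be 'strict' or 'tolerance'")
    if (
        panel_rep1.sample_ids != panel_rep2.sample_ids
        or panel_rep1.locus_ids != panel_rep2.locus_ids
    ):
        raise ValueError("replicate panels must share samples and loci")
    mism = (panel_rep1.presence != panel_rep2.presence).sum(axis=0)
    n, m = panel_rep1.presence.shape
    error_rate = float(mism.sum()) / (n * m) if n * m else 0.0
    if mode == "strict":
        keep = np.flatnonzero(mism == 0)
    else:
        keep = np.flatnonzero(mism / n <= max_mismatch_fraction)
    report = ReproducibilityReport(
        n_loci_in=m,
        n_loci_retained=keep.size,
        per_locus_mismatches=mism,
        error_rate=error_rate,
    )
    return panel_rep1.subset_loci(keep), report


def align_panels(
    hpa: FragmentPanel, msp: FragmentPanel
) -> tuple[FragmentPanel, FragmentPanel]:
    """Restrict both panels to their shared loci, preserving HpaII order.

    Sample identifiers must already agree; loci are matched by identifier
    (independently applied filters may have dropped different loci from
    the two panels).
    """
    if hpa.sample_ids != msp.sample_ids:
        raise ValueError("HpaII and MspI panels must share sample_ids")
    shared = set(hpa.locus_ids) & set(msp.locus_ids)
    h_idx = [i for i, lid in enumerate(hpa.locus_ids) if lid in shared]
    order = [hpa.locus_ids[i] for i in h_idx]
    m_pos = {lid: i for i, lid in enumerate(msp.locus_ids)}
    m_idx = [m_pos[lid] for lid in order]
    return hpa.subset_loci(h_idx), msp.subset_loci(m_idx)


@dataclass
class EpilocusMatrix:
    """Sample x locus matrix of four-state epilocus calls.

    ``states`` holds :class:`EpilocusState` codes.  The expanded binary
    view splits every locus into three 0/1 subcolumns named
    ``<locus>.n`` / ``<locus>.i`` / ``<locus>.e``; an ambiguous call
    expands to ``(0, 0, 0)``.
    """

    sample_ids: list
    locus_ids: list
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2:
            raise ValueError("states must be 2-D")
        if self.states.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError("states shape does not match sample/locus ids")
        if not np.isin(self.states, [0, 1, 2, 3]).all():
            raise ValueError("states must be EpilocusState codes 0..3")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def expanded(self, drop_unobserved: bool = False) -> pd.DataFrame:
        """Return the expanded binary view as a DataFrame.

        Parameters
        ----------
        drop_unobserved :
            If true, subcolumns in which no sample shows presence are
            dropped; the surviving columns are the scorable epiloci that
            downstream statistics consume.
        """
        flat = _EXPANSION[self.states]  # (n, L, 3)
        n = self.n_samples
        data = flat.reshape(n, -1)
        cols = [
            f"{lid}.{suf}" for lid in self.locus_ids for suf in PANEL_SUFFIXES
        ]
        df = pd.DataFrame(data, index=pd.Index(self.sample_ids, name="sample_id"),
                          columns=cols)
        if drop_unobserved:
            df = df.loc[:, df.sum(axis=0) > 0]
        return df

    def state_strings(self) -> pd.DataFrame:
        """The matrix rendered as the classic three-digit string codes."""
        codes = np.array([STATE_CODES[EpilocusState(k)] for k in range(4)])
        return pd.DataFrame(
            codes[self.states],
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.locus_ids,
        )

    def state_counts(self) -> dict:
        """Total count of each state over the whole matrix."""
        return {
            EpilocusState(k): int((self.states == k).sum()) for k in range(4)
        }

    def to_tsv(self, path, sep: str = "\t") -> None:
        self.state_strings().to_csv(path, sep=sep)


def build_epilocus_matrix(
    hpa: FragmentPanel, msp: FragmentPanel
) -> EpilocusMatrix:
    """Score aligned HpaII/MspI panels into an :class:`EpilocusMatrix`."""
    if hpa.sample_ids != msp.sample_ids:
        raise ValueError("HpaII and MspI panels must share sample_ids")
    if hpa.locus_ids != msp.locus_ids:
        raise ValueError(
            "HpaII and MspI panels must share locus ordering; "
            "use align_panels() first"
        )
    states = score_condition(hpa.presence, msp.presence)
    return EpilocusMatrix(
        sample_ids=list(hpa.sample_ids),
        locus_ids=list(hpa.locus_ids),
        states=states,
    )


def panel_types(columns) -> np.ndarray:
    """Map expanded-view column names to their panel suffix ('n'/'i'/'e')."""
    out = []
    for col in columns:
        _, _, suf = str(col).rpartition(".")
        if suf not in PANEL_SUFFIXES:
            raise ValueError(f"column {col!r} lacks a .n/.i/.e panel suffix")
        out.append(suf)
    return np.asarray(out)
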