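"""Synthetic dual-enzyme MSAP studies.

Generates fragment panels (two replicates per enzyme), sample metadata and
the generating truth for a study with the structure the downstream
statistics assume: four combined groups (two cytotypes x reproduction
modes), three epilocus panels with group-specific presence frequencies,
optional planted environmental-candidate and group-private loci, and
spatially unstructured residual variation.

Presence/absence is simulated directly at the epilocus level: each
simulated locus carries exactly one informative epilocus type (its focal
state), with absence encoded as the ambiguous condition.  Scoring the
generated panels at zero noise therefore recovers the generating state
matrix exactly, and the scorable epilocus counts per panel equal the
configured panel sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .scoring import (
    Enzyme,
    EpilocusMatrix,
    EpilocusState,
    FragmentPanel,
    PANEL_SUFFIXES,
    STATE_TO_BITS,
)

__all__ = [
    "CandidateLocus",
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_metadata",
    "simulate_states",
    "states_to_panels",
    "simulate_study",
    "write_study",
    "GROUP_INFO",
    "ENV_VARIABLES",
]

#: combined group -> (ploidy, reproduction mode)
GROUP_INFO = {
    "2xS": ("2x", "sexual"),
    "2xM": ("2x", "mixed"),
    "4xM": ("4x", "mixed"),
    "4xA": ("4x", "apomictic"),
}

#: metadata columns usable as environmental predictors
ENV_VARIABLES = ("elevation", "amt", "ap")

#: focal epilocus suffix -> generating state
_FOCAL_STATE = {
    "n": EpilocusState.NONMETH,
    "i": EpilocusState.INTERNAL,
    "e": EpilocusState.EXTERNAL,
}

# default within-group polymorphic fractions per panel, chosen so that the
# apomictic tetraploids carry the signature contrast: depauperate
# nonmethylated/external variation, elevated internal variation
_DEFAULT_POLY_FRACTION = {
    "2xS": {"n": 0.61, "e": 0.69, "i": 0.59},
    "2xM": {"n": 0.32, "e": 0.48, "i": 0.31},
    "4xM": {"n": 0.71, "e": 0.64, "i": 0.45},
    "4xA": {"n": 0.18, "e": 0.16, "i": 0.70},
}

_DEFAULT_ELEVATION = {
    "2xS": (1300.0, 2100.0),
    "2xM": (1400.0, 2100.0),
    "4xM": (1700.0, 2600.0),
    "4xA": (2000.0, 2800.0),
}


@dataclass
class CandidateLocus:
    """A planted logistic dependence of one locus on one variable."""

    locus: int
    variable: str
    beta0: float
    beta1: float


@dataclass
class SimulationConfig:
    """All knobs of a simulated study.

    Defaults reproduce the reference design: 123 samples in groups of
    41/6/45/31 over 48 populations, and 268/378/442 epiloci in the
    nonmethylated/external/internal panels (1088 in total).
    """

    group_sizes: dict = field(
        default_factory=lambda: {"2xS": 41, "2xM": 6, "4xM": 45, "4xA": 31}
    )
    panel_sizes: dict = field(
        default_factory=lambda: {"n": 268, "e": 378, "i": 442}
    )
    poly_fraction: dict = field(
        default_factory=lambda: {
            g: dict(v) for g, v in _DEFAULT_POLY_FRACTION.items()
        }
    )
    poly_freq_range: tuple = (0.15, 0.85)
    mono_present_prob: float = 0.5
    n_populations: int = 48
    lon_range_2x: tuple = (5.5, 8.5)
    lon_range_4x: tuple = (6.5, 16.0)
    lat_range: tuple = (44.0, 47.5)
    elevation_ranges: dict = field(
        default_factory=lambda: {g: v for g, v in _DEFAULT_ELEVATION.items()}
    )
    amt_intercept: float = 14.0
    lapse_rate: float = 0.0065
    amt_noise_sd: float = 0.5
    ap_range: tuple = (600.0, 1600.0)
    candidate_loci: list = field(default_factory=list)
    private_loci: list = field(default_factory=list)
    noise_rate: float = 0.0
    replicate_discordance_rate: float = 0.0
    size_range: tuple = (100, 600)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUP_INFO:
                raise ValueError(f"unknown group {g!r}")
            if n < 1:
                raise ValueError("group sizes must be >= 1")
        for suf in self.panel_sizes:
            if suf not in PANEL_SUFFIXES:
                raise ValueError(f"unknown panel suffix {suf!r}")
        for g, panels in self.poly_fraction.items():
            for suf, p in panels.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError("poly_fraction entries must lie in [0, 1]")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")
        if not 0.0 <= self.replicate_discordance_rate <= 1.0:
            raise ValueError("replicate_discordance_rate must lie in [0, 1]")
        self.candidate_loci = [
            c if isinstance(c, CandidateLocus) else CandidateLocus(**c)
            for c in self.candidate_loci
        ]
        for c in self.candidate_loci:
            if c.variable not in ENV_VARIABLES:
                raise ValueError(
                    f"candidate locus {c.locus} references unknown variable "
                    f"{c.variable!r}; expected one of {ENV_VARIABLES}"
                )
        self.private_loci = [tuple(p) for p in self.private_loci]
        for _, g in self.private_loci:
            if g not in self.group_sizes:
                raise ValueError(f"private locus references unknown group {g!r}")

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())

    @property
    def n_loci(self) -> int:
        return sum(self.panel_sizes.values())


@dataclass
class SimulatedStudy:
    """A complete simulated experiment plus its generating truth."""

    config: SimulationConfig
    metadata: pd.DataFrame
    states: EpilocusMatrix
    locus_types: np.ndarray
    truth: dict
    hpa_rep1: FragmentPanel
    hpa_rep2: FragmentPanel
    msp_rep1: FragmentPanel
    msp_rep2: FragmentPanel


def _allocate(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of ``total`` integers by ``weights``."""
    raw = total * weights / weights.sum()
    out = np.floor(raw).astype(int)
    out = np.maximum(out, 1)
    while out.sum() > total:
        out[np.argmax(out)] -= 1
    rem = raw - np.floor(raw)
    while out.sum() < total:
        i = int(np.argmax(rem))
        out[i] += 1
        rem[i] = -1
    return out


def simulate_metadata(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate populations, coordinates and environmental covariates.

    Samples inherit the coordinates, elevation and climate of their
    population.  Annual mean temperature decreases deterministically with
    elevation (lapse-rate model) plus Gaussian noise, so elevation and
    temperature are correlated; annual precipitation is an independent
    draw.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    groups = list(config.group_sizes)
    sizes = np.array([config.group_sizes[g] for g in groups], dtype=float)
    pops_per_group = _allocate(config.n_populations, sizes)

    pop_rows = []
    pop_id = 0
    for g, n_pops in zip(groups, pops_per_group):
        ploidy, _ = GROUP_INFO[g]
        lon_lo, lon_hi = (
            config.lon_range_2x if ploidy == "2x" else config.lon_range_4x
        )
        elev_lo, elev_hi = config.elevation_ranges[g]
        for _ in range(n_pops):
            pop_id += 1
            lon = rng.uniform(lon_lo, lon_hi)
            lat = rng.uniform(*config.lat_range)
            elev = rng.uniform(elev_lo, elev_hi)
            amt = (
                config.amt_intercept
                - config.lapse_rate * elev
                + rng.normal(0.0, config.amt_noise_sd)
            )
            ap = rng.uniform(*config.ap_range)
            pop_rows.append(
                {
                    "population": f"P{pop_id:02d}",
                    "group": g,
                    "longitude": lon,
                    "latitude": lat,
                    "elevation": elev,
                    "amt": amt,
                    "ap": ap,
                }
            )
    pops = pd.DataFrame(pop_rows)

    rows = []
    sample_no = 0
    for g in groups:
        g_pops = pops[pops["group"] == g].reset_index(drop=True)
        ploidy, mode = GROUP_INFO[g]
        for k in range(config.group_sizes[g]):
            sample_no += 1
            pop = g_pops.iloc[k % len(g_pops)]
            rows.append(
                {
                    "sample_id": f"S{sample_no:03d}",
                    "population": pop["population"],
                    "group": g,
                    "ploidy": ploidy,
                    "reproduction_mode": mode,
                    "longitude": pop["longitude"],
                    "latitude": pop["latitude"],
                    "elevation": pop["elevation"],
                    "amt": pop["amt"],
                    "ap": pop["ap"],
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (x - x.mean()) / sd


def simulate_states(
    config: SimulationConfig,
    metadata: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[EpilocusMatrix, np.ndarray, dict]:
    """Simulate the four-state matrix and return it with its truth.

    For ordinary loci the focal epilocus presence is Bernoulli with a
    group-specific frequency (polymorphic loci draw a frequency inside
    ``poly_freq_range``, monomorphic loci are fixed present or absent).
    Candidate loci replace the group model with a logistic dependence on a
    standardized environmental variable; private loci are present only in
    their target group.  Sampling is independent across samples given the
    covariates, so there is no residual spatial autocorrelation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    groups = list(config.group_sizes)
    n = len(metadata)
    group_of = metadata["group"].to_numpy()
    large_groups = [g for g in groups if config.group_sizes[g] >= 20]

    locus_types = np.concatenate(
        [np.repeat(suf, config.panel_sizes.get(suf, 0)) for suf in ("n", "e", "i")]
    )
    L = locus_types.size
    locus_ids = [f"L{i + 1:04d}" for i in range(L)]

    special = {c.locus: c for c in config.candidate_loci}
    private = dict(config.private_loci)
    for idx in list(special) + list(private):
        if not 0 <= idx < L:
            raise ValueError(f"locus index {idx} out of range 0..{L - 1}")

    lo, hi = config.poly_freq_range
    freqs = np.zeros((L, len(groups)))
    for j, g in enumerate(groups):
        is_poly = rng.random(L) < np.array(
            [config.poly_fraction[g].get(t, 0.5) for t in locus_types]
        )
        p_poly = rng.uniform(lo, hi, size=L)
        p_mono = (rng.random(L) < config.mono_present_prob).astype(float)
        freqs[:, j] = np.where(is_poly, p_poly, p_mono)

    # guarantee scorability: if a locus has a non-negligible chance of
    # never being observed in any sample, fix it present in one of the
    # larger groups (an unobserved fragment could not have been scored)
    if not large_groups:
        biggest = max(groups, key=lambda g: config.group_sizes[g])
        large_groups = [biggest]
    sizes_arr = np.array([config.group_sizes[g] for g in groups], dtype=float)
    force_choice = rng.integers(0, len(large_groups), size=L)
    log_p_unobserved = (
        np.log1p(-np.clip(freqs, 0.0, 1.0 - 1e-12)) * sizes_arr[None, :]
    ).sum(axis=1)
    for i in np.flatnonzero(log_p_unobserved > np.log(1e-9)):
        if i in special or i in private:
            continue
        freqs[i, groups.index(large_groups[force_choice[i]])] = 1.0

    for i, g in private.items():
        for j, other in enumerate(groups):
            freqs[i, j] = 0.0
        p = rng.uniform(max(lo, 0.3), hi)
        freqs[i, groups.index(g)] = p

    group_idx = np.array([groups.index(g) for g in group_of])
    prob = freqs[:, group_idx].T  # (n, L)

    for i, cand in special.items():
        z = _standardize(metadata[cand.variable].to_numpy(dtype=float))
        prob[:, i] = expit(cand.beta0 + cand.beta1 * z)
        freqs[i, :] = np.nan

    presence = (rng.random((n, L)) < prob).astype(np.uint8)

    # private loci must actually be observed in their target group
    for i, g in private.items():
        members = np.flatnonzero(group_of == g)
        if presence[members, i].sum() == 0:
            presence[rng.choice(members), i] = 1

    focal = np.array([_FOCAL_STATE[t] for t in locus_types], dtype=np.int8)
    states = np.where(presence == 1, focal[None, :], EpilocusState.AMBIG)

    truth = {
        "locus_types": locus_types.tolist(),
        "group_order": groups,
        "group_frequencies": freqs.tolist(),
        "candidate_loci": [asdict(c) for c in config.candidate_loci],
        "private_loci": [[i, g] for i, g in config.private_loci],
    }
    matrix = EpilocusMatrix(
        sample_ids=list(metadata.index), locus_ids=locus_ids, states=states
    )
    return matrix, locus_types, truth


def states_to_panels(
    states: EpilocusMatrix,
    noise_rate: float = 0.0,
    replicate_discordance_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
    fragment_sizes: np.ndarray | None = None,
    size_range: tuple = (100, 600),
) -> dict:
    """Invert the scoring truth table into dual-enzyme fragment panels.

    Each state maps to its ``(hpa, msp)`` bit pair; independent bit flips
    are applied at ``noise_rate``, and replicate 2 of each enzyme differs
    from replicate 1 by further flips at ``replicate_discordance_rate``.

    Returns
    -------
    dict
        ``{"hpa": (rep1, rep2), "msp": (rep1, rep2)}`` of
        :class:`~epimsap.scoring.FragmentPanel`.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    hpa_bit = np.zeros(4, dtype=np.uint8)
    msp_bit = np.zeros(4, dtype=np.uint8)
    for state, (h, m) in STATE_TO_BITS.items():
        hpa_bit[state] = h
        msp_bit[state] = m
    if fragment_sizes is None:
        fragment_sizes = rng.integers(
            size_range[0], size_range[1] + 1, size=states.n_loci
        ).astype(float)

    out = {}
    for enzyme, bits in (("hpa", hpa_bit), ("msp", msp_bit)):
        rep1 = bits[states.states]
        if noise_rate > 0:
            rep1 = rep1 ^ (rng.random(rep1.shape) < noise_rate)
        rep2 = rep1.copy()
        if replicate_discordance_rate > 0:
            rep2 = rep2 ^ (rng.random(rep2.shape) < replicate_discordance_rate)
        enz = Enzyme.HPAII if enzyme == "hpa" else Enzyme.MSPI
        out[enzyme] = tuple(
            FragmentPanel(
                enzyme=enz,
                sample_ids=list(states.sample_ids),
                locus_ids=list(states.locus_ids),
                presence=rep.astype(np.uint8),
                fragment_sizes=fragment_sizes,
            )
            for rep in (rep1, rep2)
        )
    return out


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Run the full generator: metadata, states, panels, truth."""
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    metadata = simulate_metadata(config, rng)
    states, locus_types, truth = simulate_states(config, metadata, rng)
    panels = states_to_panels(
        states,
        noise_rate=config.noise_rate,
        replicate_discordance_rate=config.replicate_discordance_rate,
        rng=rng,
        size_range=config.size_range,
    )
    return SimulatedStudy(
        config=config,
        metadata=metadata,
        states=states,
        locus_types=locus_types,
        truth=truth,
        hpa_rep1=panels["hpa"][0],
        hpa_rep2=panels["hpa"][1],
        msp_rep1=panels["msp"][0],
        msp_rep2=panels["msp"][1],
    )


def write_study(study: SimulatedStudy, outdir) -> list:
    """Write the four panel files, the metadata table and the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, panel in (
        ("hpa_rep1.tsv", study.hpa_rep1),
        ("hpa_rep2.tsv", study.hpa_rep2),
        ("msp_rep1.tsv", study.msp_rep1),
        ("msp_rep2.tsv", study.msp_rep2),
    ):
        panel.to_tsv(outdir / name)
        written.append(outdir / name)
    meta_path = outdir / "metadata.tsv"
    study.metadata.to_csv(meta_path, sep="\t")
    written.append(meta_path)
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(study.truth, indent=1))
    written.append(truth_path)
    return written
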