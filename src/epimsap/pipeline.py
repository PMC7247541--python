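"""End-to-end orchestration: config, validation, staged pipeline, outputs.

``run_pipeline`` executes score -> diversity -> differentiation -> spatial
-> environmental association from a single config and writes one TSV per
result family, each carrying a comment header with the software version,
the config hash and the seed, so reruns are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diversity as dv
from . import differentiation as df_
from . import env_assoc as ea
from . import spatial as sp
from .scoring import (
    Enzyme,
    FragmentPanel,
    align_panels,
    build_epilocus_matrix,
    filter_reproducibility,
    filter_size_range,
    panel_types,
    PANEL_NAMES,
    PANEL_SUFFIXES,
)
from .simulate import GROUP_INFO, SimulationConfig, simulate_study

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "ValidationError",
    "validate_inputs",
    "run_pipeline",
]

log = logging.getLogger("epimsap")


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""


class ValidationError(ValueError):
    """Collected input-validation failures."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serializable to YAML."""

    simulate: dict | None = None
    inputs: dict | None = None
    min_bp: int = 100
    max_bp: int = 600
    reproducibility_mode: str = "strict"
    max_mismatch_fraction: float = 0.0
    group_column: str = "group"
    level1_column: str = "ploidy"
    level2_column: str = "reproduction_mode"
    variables: list = field(default_factory=lambda: ["elevation", "amt", "ap"])
    n_permutations: int = 999
    alpha: float = 0.05
    adjust_method: str = "holm"
    env_correction: str = "bonferroni"
    nmds_restarts: int = 20
    knn: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ValueError(
                "config must provide either a 'simulate' block or 'inputs'"
            )
        if self.min_bp >= self.max_bp:
            raise ValueError("min_bp must be smaller than max_bp")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_inputs(panels: list, metadata: pd.DataFrame) -> list:
    """Check panel/metadata concordance; raise with ALL problems at once.

    Returns the (empty) list of problems on success so callers can log it.
    """
    problems = []
    ref = panels[0]
    for p in panels[1:]:
        if p.sample_ids != ref.sample_ids:
            problems.append(
                f"{p.enzyme.value} panel sample_ids differ from "
                f"{ref.enzyme.value} panel"
            )
    meta_samples = set(map(str, metadata.index))
    missing = [s for s in ref.sample_ids if s not in meta_samples]
    if missing:
        problems.append(
            f"samples in panels missing from metadata: {missing[:10]}"
        )
    for col in ("group", "longitude", "latitude"):
        if col not in metadata.columns:
            problems.append(f"metadata lacks required column {col!r}")
    if "latitude" in metadata.columns:
        lat = pd.to_numeric(metadata["latitude"], errors="coerce")
        if lat.isna().any() or (lat.abs() > 90).any():
            problems.append("metadata latitude values invalid")
    if "group" in metadata.columns:
        groups = set(metadata["group"].astype(str))
        if not groups <= set(GROUP_INFO) and not (
            {"ploidy", "reproduction_mode"} <= set(metadata.columns)
        ):
            problems.append(
                f"non-standard group labels {sorted(groups - set(GROUP_INFO))} "
                "require explicit 'ploidy' and 'reproduction_mode' columns"
            )
    if problems:
        raise ValidationError("; ".join(problems))
    return problems


def _write_tsv(frame: pd.DataFrame, path: Path, header_lines: list) -> Path:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=True)
    return path


def read_matrix(path) -> pd.DataFrame:
    """Read an expanded epilocus matrix TSV written by the pipeline."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        study = simulate_study(SimulationConfig(**sim_kwargs))
        panels = {
            "hpa": (study.hpa_rep1, study.hpa_rep2),
            "msp": (study.msp_rep1, study.msp_rep2),
        }
        return panels, study.metadata
    paths = config.inputs
    for key in ("hpa_rep1", "msp_rep1", "metadata"):
        if key not in paths:
            raise ValueError(f"inputs block lacks {key!r}")
    hpa1 = FragmentPanel.read_tsv(paths["hpa_rep1"], Enzyme.HPAII)
    msp1 = FragmentPanel.read_tsv(paths["msp_rep1"], Enzyme.MSPI)
    hpa2 = (
        FragmentPanel.read_tsv(paths["hpa_rep2"], Enzyme.HPAII)
        if "hpa_rep2" in paths
        else None
    )
    msp2 = (
        FragmentPanel.read_tsv(paths["msp_rep2"], Enzyme.MSPI)
        if "msp_rep2" in paths
        else None
    )
    metadata = read_metadata(paths["metadata"])
    return {"hpa": (hpa1, hpa2), "msp": (msp1, msp2)}, metadata


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except (PipelineError, ValidationError):
                raise
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise PipelineError(f"[{name}] {exc}") from exc
            log.info("stage %s: done", name)
            return out

        return wrapper

    return deco


@_stage("score")
def _score_stage(config, panels):
    scored = {}
    for enz, (rep1, rep2) in panels.items():
        panel = rep1
        if rep2 is not None:
            panel, report = filter_reproducibility(
                rep1, rep2,
                mode=config.reproducibility_mode,
                max_mismatch_fraction=config.max_mismatch_fraction,
            )
            log.info(
                "%s reproducibility: %d/%d loci kept (error rate %.4f)",
                enz, report.n_loci_retained, report.n_loci_in,
                report.error_rate,
            )
        if panel.fragment_sizes is not None:
            panel = filter_size_range(panel, config.min_bp, config.max_bp)
        scored[enz] = panel
    hpa, msp = align_panels(scored["hpa"], scored["msp"])
    matrix = build_epilocus_matrix(hpa, msp)
    expanded = matrix.expanded(drop_unobserved=True)
    log.info(
        "scored %d samples x %d loci -> %d scorable epiloci",
        matrix.n_samples, matrix.n_loci, expanded.shape[1],
    )
    return matrix, expanded


@_stage("diversity")
def _diversity_stage(config, expanded, metadata):
    groups = metadata.loc[expanded.index, config.group_column].to_numpy()
    table = dv.diversity_table(expanded, groups)
    counts = dv.per_individual_polymorphic_counts(expanded, groups)
    return table, counts


@_stage("differentiation")
def _differentiation_stage(config, expanded, metadata, rng):
    groups = metadata.loc[expanded.index, config.group_column].to_numpy()
    lvl1 = metadata.loc[expanded.index, config.level1_column].to_numpy()
    lvl2 = metadata.loc[expanded.index, config.level2_column].to_numpy()
    types = panel_types(expanded.columns)

    resp = df_.panel_presence_response(expanded, types)
    stacked_counts = resp["count"].to_numpy()
    sample_lvl1 = metadata.loc[resp["sample_id"], config.level1_column]
    sample_lvl2 = metadata.loc[resp["sample_id"], config.level2_column]
    anovas = [
        df_.one_factor_anova(stacked_counts, sample_lvl1, config.level1_column),
        df_.one_factor_anova(stacked_counts, sample_lvl2, config.level2_column),
        df_.one_factor_anova(stacked_counts, resp["panel"], "epilocus_panel"),
    ]
    anova_df = pd.DataFrame([dataclasses.asdict(a) for a in anovas])

    pairwise_frames = []
    for suf in PANEL_SUFFIXES:
        cols = types == suf
        counts = np.asarray(expanded)[:, cols].sum(axis=1)
        pw = df_.pairwise_group_anova(counts, groups, adjust=config.adjust_method)
        pw.insert(0, "panel", PANEL_NAMES[suf])
        pairwise_frames.append(pw)
    pairwise = pd.concat(pairwise_frames, ignore_index=True)

    seeds = rng.integers(0, 2**31 - 1, size=8)
    hier = df_.hierarchical_amova(
        expanded, lvl1, lvl2,
        n_perm=config.n_permutations, seed=int(seeds[0]),
        level1_name=config.level1_column, level2_name=config.level2_column,
    )
    amova_rows = []
    t = hier.table.copy()
    t.insert(0, "analysis", "hierarchical")
    t.insert(1, "panel", "all")
    amova_rows.append(t)
    phis = []
    for i, suf in enumerate(("all",) + PANEL_SUFFIXES):
        sub = (
            expanded
            if suf == "all"
            else expanded.loc[:, types == suf]
        )
        res = df_.amova_phist(
            sub, groups, n_perm=config.n_permutations, seed=int(seeds[1 + i])
        )
        t = res.table.copy()
        t.insert(0, "analysis", "one_level")
        t.insert(1, "panel", PANEL_NAMES.get(suf, "all"))
        amova_rows.append(t)
        phis.append(
            {"panel": PANEL_NAMES.get(suf, "all"),
             "phi_st": res.phi["phi_st"], "p": res.p_values["phi_st"]}
        )
    amova_table = pd.concat(amova_rows, ignore_index=True)
    phi_table = pd.DataFrame(phis)

    frac, locus_table = df_.locus_by_locus_amova(
        expanded, groups, alpha=config.alpha,
        n_perm=config.n_permutations, seed=int(seeds[5]),
    )
    ord_res = df_.nmds(
        expanded, k=2, seed=int(seeds[6]), n_restarts=config.nmds_restarts
    )
    return {
        "anova": anova_df,
        "pairwise": pairwise,
        "amova": amova_table,
        "phi": phi_table,
        "hier": hier,
        "locus_fraction": frac,
        "locus_table": locus_table,
        "nmds": ord_res,
    }


@_stage("spatial")
def _spatial_stage(config, expanded, metadata, rng):
    meta = metadata.loc[expanded.index]
    groups = meta[config.group_column].to_numpy()
    lvl1 = meta[config.level1_column].to_numpy()
    types = panel_types(expanded.columns)
    seeds = rng.integers(0, 2**31 - 1, size=64)

    d_epi = sp.mismatch_distances(expanded)
    d_geo = sp.geographic_distances(
        meta["longitude"].to_numpy(), meta["latitude"].to_numpy()
    )
    mantel_rows = []
    res = sp.stratified_mantel(
        d_epi, d_geo, strata=lvl1,
        n_perm=config.n_permutations, seed=int(seeds[0]),
    )
    mantel_rows.append(
        {"scope": "all (stratified by cytotype)", "r": res.r, "p": res.p,
         "n_perm": res.n_perm}
    )
    for k, lv in enumerate(pd.unique(lvl1)):
        members = lvl1 == lv
        sub_epi = d_epi[np.ix_(members, members)]
        sub_geo = d_geo[np.ix_(members, members)]
        res = sp.stratified_mantel(
            sub_epi, sub_geo, n_perm=config.n_permutations,
            seed=int(seeds[1 + k]),
        )
        mantel_rows.append(
            {"scope": f"within {lv}", "r": res.r, "p": res.p,
             "n_perm": res.n_perm}
        )
    mantel = pd.DataFrame(mantel_rows)

    moran_rows = []
    geary_frames = []
    seed_i = 8
    for g in pd.unique(groups):
        members = np.flatnonzero(groups == g)
        sub = expanded.iloc[members]
        d_sub = d_geo[np.ix_(members, members)]
        weights = sp.inverse_distance_weights(d_sub, k=config.knn)
        results = []
        for suf in PANEL_SUFFIXES:
            block = sub.loc[:, types == suf]
            res = sp.morans_i_panel(
                block, weights, n_perm=config.n_permutations,
                seed=int(seeds[seed_i]),
            )
            seed_i += 1
            results.append((suf, res))
        sp.adjust_moran_p([r for _, r in results], method=config.adjust_method)
        for suf, res in results:
            moran_rows.append(
                {"group": g, "panel": PANEL_NAMES[suf], "I_obs": res.i_obs,
                 "I_est": res.i_est, "p": res.p, "adjusted_p": res.adjusted_p,
                 "n_loci": res.n_loci, "weights": res.scheme}
            )
        geary = sp.local_geary_panel(sub, weights)
        gf = geary.c.to_frame()
        gf.insert(0, "group", g)
        gf["above_threshold"] = geary.c > geary.threshold
        geary_frames.append(gf)
    moran = pd.DataFrame(moran_rows)
    geary_table = pd.concat(geary_frames)
    return mantel, moran, geary_table


@_stage("envassoc")
def _envassoc_stage(config, expanded, metadata):
    meta = metadata.loc[expanded.index]
    screen = ea.screen_all(
        expanded, meta, config.variables,
        alpha=config.alpha, correction=config.env_correction,
    )
    return screen


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write the report bundle to ``outdir``.

    Returns a dict mapping output names to paths.  Deterministic under a
    fixed config (seed included), and every output file carries the
    config hash and package version.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    head = [
        f"epimsap v{__version__}",
        f"config_sha256 {config.sha256()}",
        f"seed {config.seed}",
    ]
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )

    try:
        panels, metadata = _load_inputs(config)
    except Exception as exc:
        raise PipelineError(f"[inputs] {exc}") from exc
    validate_inputs(
        [p for pair in panels.values() for p in pair if p is not None],
        metadata,
    )

    matrix, expanded = _score_stage(config, panels)
    rng = np.random.default_rng(config.seed)

    outputs = {}
    outputs["states"] = _write_tsv(
        matrix.state_strings(), outdir / "epiloci_states.tsv", head
    )
    outputs["expanded"] = _write_tsv(
        expanded, outdir / "epiloci_expanded.tsv", head
    )
    meta_out = metadata.loc[expanded.index]
    outputs["metadata"] = _write_tsv(meta_out, outdir / "metadata.tsv", head)

    table, counts = _diversity_stage(config, expanded, metadata)
    outputs["diversity"] = _write_tsv(
        table.set_index("group"), outdir / "diversity.tsv", head
    )
    outputs["poly_counts"] = _write_tsv(
        counts.to_frame(), outdir / "polymorphic_counts.tsv", head
    )

    diff = _differentiation_stage(config, expanded, metadata, rng)
    outputs["anova"] = _write_tsv(
        diff["anova"].set_index("factor"), outdir / "anova.tsv", head
    )
    outputs["anova_pairwise"] = _write_tsv(
        diff["pairwise"].set_index("panel"), outdir / "anova_pairwise.tsv", head
    )
    outputs["amova"] = _write_tsv(
        diff["amova"].set_index("analysis"), outdir / "amova.tsv",
        head + [f"n_permutations {config.n_permutations}",
                "locus_by_locus_significant_fraction "
                f"{diff['locus_fraction']:.6f}"],
    )
    outputs["phi"] = _write_tsv(
        diff["phi"].set_index("panel"), outdir / "phi_st.tsv", head
    )
    outputs["locus_amova"] = _write_tsv(
        diff["locus_table"].set_index("locus"), outdir / "locus_amova.tsv", head
    )
    outputs["nmds"] = _write_tsv(
        diff["nmds"].coordinates, outdir / "nmds.tsv",
        head + [f"stress {diff['nmds'].stress:.6f}",
                f"metric {diff['nmds'].metric}"],
    )

    mantel, moran, geary = _spatial_stage(config, expanded, metadata, rng)
    outputs["mantel"] = _write_tsv(
        mantel.set_index("scope"), outdir / "mantel.tsv", head
    )
    outputs["moran"] = _write_tsv(
        moran.set_index("group"), outdir / "moran.tsv", head
    )
    outputs["geary"] = _write_tsv(geary, outdir / "geary.tsv", head)

    screen = _envassoc_stage(config, expanded, metadata)
    outputs["envassoc"] = _write_tsv(
        screen.results.set_index("locus"), outdir / "envassoc.tsv",
        head + [f"alpha {screen.alpha}", f"correction {screen.correction}",
                f"n_tests {screen.n_tests}"],
    )
    outputs["envassoc_summary"] = _write_tsv(
        screen.counts.set_index("panel")
        if len(screen.counts)
        else screen.counts,
        outdir / "envassoc_summary.tsv", head,
    )
    log.info("pipeline complete: %d outputs in %s", len(outputs), outdir)
    return outputs
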