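"""Tabular file formats, run configuration, and the end-to-end pipeline.

Everything is plain delimiter-separated text: the artifact begins after
regional volume extraction, so no imaging formats are involved.  Region
labels default to the 90-region AAL parcellation shipped with the package;
arbitrary label lists are accepted for other parcellations, with the 1/N
nodal threshold adapting automatically.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import ChoiceSet, DiscountFit, GroupAssignment, fit_discounting, median_split
from .covariance import (
    CovarianceNetwork,
    MorphometryTable,
    binarize_at_sparsity,
    covariance_matrix,
    residualize,
    sparsity_grid,
    zero_negatives,
)
from .graph_metrics import nodal_metrics, small_world
from .permutation import (
    PermutationResult,
    nodal_threshold,
    permutation_test_global,
    permutation_test_nodal,
)

logger = logging.getLogger("sconet")

CHOICE_COLUMNS = ["subject_id", "immediate_amount", "delayed_amount", "delay_days", "chose_delayed"]


def aal90_labels() -> list[str]:
    """The 90 AAL region labels (45 per hemisphere, left/right interleaved)."""
    text = importlib.resources.files("sconet.data").joinpath("aal90_labels.txt").read_text()
    labels = text.split()
    assert len(labels) == 90
    return labels


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def read_choices(path: str | Path) -> dict[str, ChoiceSet]:
    """Load a choice log into per-subject ChoiceSets, preserving file order."""
    df = _read_table(path, CHOICE_COLUMNS)
    for col in CHOICE_COLUMNS[1:]:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(f"{path}: non-numeric value in column {col}, row {bad}")
    out: dict[str, ChoiceSet] = {}
    for sid, g in df.groupby("subject_id", sort=False):
        out[str(sid)] = ChoiceSet(
            subject_id=str(sid),
            immediate_amount=g["immediate_amount"].to_numpy(float),
            delayed_amount=g["delayed_amount"].to_numpy(float),
            delay=g["delay_days"].to_numpy(float),
            chose_delayed=g["chose_delayed"].to_numpy(float),
        )
    return out


def write_choices(sets: list[ChoiceSet], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "subject_id": cs.subject_id,
                "immediate_amount": cs.immediate_amount,
                "delayed_amount": cs.delayed_amount,
                "delay_days": cs.delay,
                "chose_delayed": cs.chose_delayed.astype(int),
            }
        )
        for cs in sets
    ]
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def write_fits(fits: list[DiscountFit], assignment: GroupAssignment | None, path: str | Path) -> None:
    rows = []
    for f in fits:
        rows.append(
            {
                "subject_id": f.subject_id,
                "k": f.k,
                "log_k": f.log_k,
                "log10_k": f.log10_k,
                "beta": f.beta,
                "neg_log_lik": f.neg_log_lik,
                "degenerate": int(f.degenerate),
                "group": assignment.label(f.subject_id) if assignment else "none",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_morphometry(
    volumes_path: str | Path,
    covariates_path: str | Path,
    groups_path: str | Path | None = None,
) -> MorphometryTable:
    """Load a subject x region volume table plus companion covariates.

    The volume table's first column is subject_id; remaining columns are
    region labels.  Covariates are keyed by subject_id with columns age,
    sex, education, tiv.  An optional groups table (subject_id, group)
    carries high/low labels.
    """
    vols = _read_table(volumes_path, ["subject_id"])
    if vols["subject_id"].duplicated().any():
        dup = vols.loc[vols["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"{volumes_path}: duplicate subject_id {dup!r}")
    regions = [c for c in vols.columns if c != "subject_id"]
    mat = vols[regions]
    if mat.isna().any().any():
        r, c = np.argwhere(mat.isna().to_numpy())[0]
        raise ValueError(
            f"{volumes_path}: missing volume at subject {vols['subject_id'].iloc[r]}, region {regions[c]}"
        )
    for c in regions:
        if not pd.api.types.is_numeric_dtype(mat[c]):
            raise ValueError(f"{volumes_path}: non-numeric cell in region column {c}")
    cov = _read_table(covariates_path, ["subject_id", "age", "sex", "education", "tiv"])
    cov = cov.set_index("subject_id")
    subjects = [str(s) for s in vols["subject_id"]]
    missing = [s for s in subjects if s not in cov.index.astype(str)]
    if missing:
        raise ValueError(f"{covariates_path}: no covariates for subject(s) {missing[:5]}")
    cov.index = cov.index.astype(str)
    group = np.array(["none"] * len(subjects), dtype=object)
    if groups_path is not None:
        gdf = _read_table(groups_path, ["subject_id", "group"]).set_index("subject_id")
        gdf.index = gdf.index.astype(str)
        group = np.array([str(gdf["group"].get(s, "none")) for s in subjects], dtype=object)
    return MorphometryTable(
        subjects=subjects,
        regions=regions,
        volumes=mat.to_numpy(float),
        covariates=cov.loc[subjects, ["age", "sex", "education", "tiv"]],
        group=group,
    )


def write_morphometry(table: MorphometryTable, volumes_path, covariates_path, groups_path=None) -> None:
    vols = pd.DataFrame(table.volumes, columns=table.regions)
    vols.insert(0, "subject_id", table.subjects)
    vols.to_csv(volumes_path, sep="\t", index=False)
    cov = table.covariates.copy()
    cov.insert(0, "subject_id", table.subjects)
    cov.to_csv(covariates_path, sep="\t", index=False)
    if groups_path is not None:
        pd.DataFrame({"subject_id": table.subjects, "group": table.group}).to_csv(
            groups_path, sep="\t", index=False
        )


def write_network(net: CovarianceNetwork, adjacency_path, edges_path=None) -> None:
    """Square adjacency matrix with region-label header, plus an edge list."""
    mat = net.adjacency if net.adjacency is not None else net.weights
    pd.DataFrame(mat, index=net.labels, columns=net.labels).to_csv(adjacency_path, sep="\t")
    if edges_path is not None:
        iu, ju = np.triu_indices(net.n_nodes, k=1)
        pd.DataFrame(
            {
                "region_a": [net.labels[i] for i in iu],
                "region_b": [net.labels[j] for j in ju],
                "weight": net.weights[iu, ju],
                "retained": (net.adjacency[iu, ju] if net.adjacency is not None else np.ones(len(iu))).astype(int),
            }
        ).to_csv(edges_path, sep="\t", index=False)


def permutation_results_frame(results: list[PermutationResult], level: str) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "level": level,
            "metric": r.metric,
            "sparsity" if level == "global" else "region": r.unit,
            "observed_diff": r.observed_diff,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p": r.p_value,
            "reps": r.repetitions,
            "n_failed": r.n_failed,
        }
        row.update(r.flags)
        rows.append(row)
    return pd.DataFrame(rows)


def write_with_metadata(df: pd.DataFrame, path: str | Path, metadata: dict) -> None:
    """Write a table with run metadata embedded as commented header lines."""
    with open(path, "w") as fh:
        for k, v in metadata.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration and the end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Full pipeline settings; defaults follow the study's printed analysis.

    Sparsity 0.25-0.53 in steps of 0.01, 1,000 permutation repetitions,
    100 matched random networks for the observed small-world normalization
    (a reduced inner null count inside permutations), nodal analysis at
    sparsity 0.25 with significance at 0.05 and 1/N.
    """

    choices: str | None = None
    volumes: str | None = None
    covariates: str | None = None
    groups: str | None = None
    out_dir: str = "results"
    sparsity_low: float = 0.25
    sparsity_high: float = 0.53
    sparsity_step: float = 0.01
    nodal_sparsity: float = 0.25
    reps: int = 1000
    n_random: int = 100
    n_random_inner: int = 20
    seed: int = 0
    alpha: float = 0.05
    residualize_scope: str = "pooled"
    null_model: str = "degree_preserving"
    global_metrics: tuple[str, ...] = ("clustering", "path_length", "sigma")
    covariate_names: tuple[str, ...] = ("age", "sex", "education", "tiv")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        for key in ("global_metrics", "covariate_names"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["global_metrics"] = list(self.global_metrics)
        data["covariate_names"] = list(self.covariate_names)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @property
    def grid(self) -> list[float]:
        return sparsity_grid(self.sparsity_low, self.sparsity_high, self.sparsity_step)


@dataclass
class PipelineResult:
    fits: list[DiscountFit]
    assignment: GroupAssignment
    table: MorphometryTable
    global_results: list[PermutationResult]
    nodal_results: list[PermutationResult]
    global_metrics: pd.DataFrame
    nodal_metrics: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Behavior fits -> median split -> residualize -> networks -> metrics ->
    permutation inference, writing every stage table under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = config.grid

    # behavior stage
    choice_sets = read_choices(config.choices)
    logger.info("fitting %d subjects", len(choice_sets))
    fits = [fit_discounting(cs) for cs in choice_sets.values()]
    assignment = median_split(fits)
    write_fits(fits, assignment, out / "discounting_fits.tsv")

    # morphometry stage
    table = read_morphometry(config.volumes, config.covariates, config.groups)
    analyzed = np.array(
        [assignment.label(s) for s in table.subjects], dtype=object
    )
    table.group = analyzed
    if config.residualize_scope == "pooled":
        corrected = residualize(table, config.covariate_names)
    elif config.residualize_scope == "within_group":
        corrected = table
        parts = []
        for g in ("high", "low"):
            parts.append(residualize(table.subset(table.group == g), config.covariate_names))
        corrected = MorphometryTable(
            subjects=[s for p in parts for s in p.subjects],
            regions=list(table.regions),
            volumes=np.vstack([p.volumes for p in parts]),
            covariates=pd.concat([p.covariates for p in parts]),
            group=np.concatenate([p.group for p in parts]),
            residualized=True,
        )
    else:
        raise ValueError(f"unknown residualize_scope {config.residualize_scope!r}")

    # networks and observed topology per group
    rng = np.random.default_rng([config.seed, 90])
    global_rows, nodal_rows = [], []
    for g in ("high", "low"):
        net = zero_negatives(covariance_matrix(corrected, g))
        logger.info("group %s: zeroed %d negative correlations", g, net.n_zeroed_negative)
        for s in grid:
            b = binarize_at_sparsity(net, s)
            gm = small_world(b.adjacency, n_random=config.n_random, seed=rng, sparsity=s)
            for metric, value in (
                ("clustering", gm.clustering),
                ("path_length", gm.path_length),
                ("gamma", gm.gamma),
                ("lambda", gm.lambda_),
                ("sigma", gm.sigma),
            ):
                global_rows.append({"group": g, "sparsity": s, "metric": metric, "value": value})
            if s == grid[0]:
                write_network(b, out / f"network_{g}_s{s}.tsv", out / f"edges_{g}_s{s}.tsv")
        b = binarize_at_sparsity(net, config.nodal_sparsity)
        if np.any(b.adjacency.sum(axis=1) == 0):
            logger.warning("group %s: isolated node(s) at sparsity %.2f", g, config.nodal_sparsity)
        nm = nodal_metrics(b.adjacency, sparsity=config.nodal_sparsity)
        hubs = set(nm.hubs.tolist())
        for j, region in enumerate(table.regions):
            nodal_rows.append(
                {
                    "group": g,
                    "region": region,
                    "bc": nm.bc[j],
                    "bc_normalized": nm.bc_normalized[j],
                    "is_hub": int(j in hubs),
                }
            )
    global_df = pd.DataFrame(global_rows)
    nodal_df = pd.DataFrame(nodal_rows)
    global_df.to_csv(out / "global_metrics.tsv", sep="\t", index=False)
    nodal_df.to_csv(out / "nodal_metrics.tsv", sep="\t", index=False)

    # permutation inference
    global_results = permutation_test_global(
        corrected,
        assignment,
        grid,
        metrics=config.global_metrics,
        reps=config.reps,
        n_random_inner=config.n_random_inner,
        seed=config.seed,
    )
    nodal_results = permutation_test_nodal(
        corrected, assignment, sparsity=config.nodal_sparsity, reps=config.reps, seed=config.seed
    )
    metadata = {
        "sconet_version": __version__,
        "seed": config.seed,
        "reps": config.reps,
        "n_random": config.n_random,
        "n_random_inner": config.n_random_inner,
        "sparsity_grid": f"{config.sparsity_low}-{config.sparsity_high}/{config.sparsity_step}",
        "alpha": config.alpha,
        "nodal_threshold": nodal_threshold(table.n_regions),
        "n_failed_global": global_results[0].n_failed if global_results else 0,
        "n_failed_nodal": nodal_results[0].n_failed if nodal_results else 0,
    }
    write_with_metadata(
        pd.concat(
            [
                permutation_results_frame(global_results, "global"),
                permutation_results_frame(nodal_results, "nodal"),
            ]
        ),
        out / "permutation_results.tsv",
        metadata,
    )
    config.to_yaml(out / "manifest.yaml")
    return PipelineResult(
        fits=fits,
        assignment=assignment,
        table=corrected,
        global_results=global_results,
        nodal_results=nodal_results,
        global_metrics=global_df,
        nodal_metrics=nodal_df,
        manifest=metadata,
    )


def make_fixtures(out_dir: str | Path, seed: int = 0, scenario: str = "planted", n_cohort: int = 71) -> dict:
    """Write a complete synthetic dataset: choice logs, volumes, covariates,
    true group labels, and a ground-truth manifest.

    The cohort's true discount rates determine which subjects receive the
    high-group covariance structure, so the planted network effect aligns
    with the behavioral median split.
    """
    from .synthetic import generate_cohort_choices, generate_morphometry, scenario_configs

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(np.random.default_rng(seed).integers(2**31))
    sets, truth = generate_cohort_choices(n_cohort, seed=rng_seed)
    write_choices(sets, out / "choices.tsv")

    order = np.argsort(-truth["k_true"].to_numpy())  # descending true k
    n_high = (n_cohort + 1) // 2
    high_cfg, low_cfg = scenario_configs(scenario, seed=seed)
    from dataclasses import replace

    table = generate_morphometry(
        replace(high_cfg, n_subjects=n_high),
        replace(low_cfg, n_subjects=n_cohort - n_high),
        seed=rng_seed + 1,
    )
    ids = truth["subject_id"].to_numpy()
    table.subjects = [str(s) for s in np.concatenate([ids[order[:n_high]], ids[order[n_high:]]])]
    table.covariates.index = table.subjects
    write_morphometry(table, out / "volumes.tsv", out / "covariates.tsv", out / "groups.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    manifest = {"scenario": scenario, "seed": seed, "n_cohort": n_cohort}
    with open(out / "fixture_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return manifest
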