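"""End-to-end pipeline: readers/writers, configuration, orchestration.

Binds the stages into one reproducible run over a directory of per-subject
time-series and motion files: motion QC -> confound regression and
band-pass -> Fisher-z connectivity -> composite degree (total and
within/between) -> group permutation test -> degree–behavior correlations
(per outcome, whole sample and per group) -> post-hoc within/between
correlations at parcels associated with behavior exclusively in one group
-> degree-based LOOCV prediction.  Every stage writes a TSV and the run is
summarized in a provenance JSON (config, seed, package versions, input
checksums).
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

from . import __version__
from .behavior import group_compare
from .connectivity import (
    MEAN_FD_MAX,
    SCRUB_FD,
    clean_timeseries,
    connectivity_matrix,
    framewise_displacement,
    motion_qc,
)
from .degree import DEFAULT_DENSITIES, composite_degree, partition_degree
from .inference import correlation_permutation_test, group_permutation_test
from .prediction import cpm_loocv, cpm_significance
from .simulate import NETWORK_LABELS, Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_parcellation",
    "read_timeseries",
    "read_motion",
    "read_behavior",
    "write_matrix",
    "write_cohort",
    "load_cohort_dir",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """All analysis parameters, defaulting to the study's stated values."""

    densities: tuple[float, ...] = DEFAULT_DENSITIES
    mean_fd_max: float = MEAN_FD_MAX          # subject exclusion (mm)
    scrub_fd: float = SCRUB_FD                # volume scrubbing (mm)
    band: tuple[float, float] = (0.01, 0.08)  # Hz
    tr: float = 3.0                           # seconds
    n_perm_group: int = 5000
    n_perm_corr: int = 5000
    n_perm_cpm: int = 1000
    p_select: float = 0.01
    family_alpha: float = 0.025               # Bonferroni over two outcomes
    fdr_alpha: float = 0.05
    posthoc_alpha: float = 0.05
    exclusive_other_p: float = 0.05           # non-significance bound for the
                                              # exclusive-correlation rule
    ttest_variant: str = "pooled"
    seed: int = 0

    def validate(self) -> None:
        if self.mean_fd_max <= 0 or self.scrub_fd <= 0:
            raise ValueError("QC thresholds must be positive")
        if not (0 <= self.band[0] < self.band[1]):
            raise ValueError("invalid band")
        if not self.densities:
            raise ValueError("density sweep must be nonempty")


# ---------------------------------------------------------------------------
# readers / writers (TSV everywhere; motion as 6-column whitespace text)


def read_parcellation(path) -> pd.DataFrame:
    """Read and validate a parcellation TSV (parcel_id, parcel_label,
    network, optional x/y/z)."""
    df = pd.read_csv(path, sep="\t")
    required = {"parcel_id", "parcel_label", "network"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parcellation file missing columns {sorted(missing)}")
    dup = df["parcel_id"][df["parcel_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate parcel_id(s): {sorted(set(dup))}")
    ids = np.sort(df["parcel_id"].to_numpy())
    if not np.array_equal(ids, np.arange(1, len(df) + 1)):
        raise ValueError("parcel_ids must be contiguous 1..n")
    unknown = set(df["network"]) - set(NETWORK_LABELS)
    if unknown:
        logger.warning("unknown network label(s) %s", sorted(unknown))
    return df


def read_timeseries(path) -> pd.DataFrame:
    ts = pd.read_csv(path, sep="\t")
    if ts.isna().any().any():
        raise ValueError(f"{path}: time series contains missing values")
    return ts


def read_motion(path) -> np.ndarray:
    motion = np.loadtxt(path)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns of motion parameters")
    return motion


def read_behavior(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ValueError("behavior table needs subject_id and group columns")
    return df.set_index("subject_id")


def write_matrix(path, M: np.ndarray, labels) -> None:
    """Square matrix as TSV with a parcel-label header."""
    pd.DataFrame(M, columns=labels).to_csv(path, sep="\t", index=False)


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a simulated cohort as the pipeline's on-disk input layout."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "motion").mkdir(exist_ok=True)
    labels = cohort.parcellation["parcel_label"]
    for sid in cohort.subjects:
        pd.DataFrame(cohort.timeseries[sid], columns=labels).to_csv(
            out / "timeseries" / f"{sid}.tsv", sep="\t", index=False
        )
        np.savetxt(out / "motion" / f"{sid}.par", cohort.motion[sid], fmt="%.8f")
    cohort.parcellation.to_csv(out / "parcellation.tsv", sep="\t", index=False)
    cohort.behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    manifest = {
        "subjects": cohort.subjects,
        "groups": cohort.groups,
        "config": json.loads(json.dumps(cohort.config(), default=list)),
        "generator": f"hubdegree {__version__}",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_cohort_dir(data_dir) -> dict:
    """Load the on-disk cohort layout written by :func:`write_cohort`."""
    data_dir = Path(data_dir)
    parcellation = read_parcellation(data_dir / "parcellation.tsv")
    behavior = read_behavior(data_dir / "behavior.tsv")
    subjects = sorted(p.stem for p in (data_dir / "timeseries").glob("*.tsv"))
    if not subjects:
        raise FileNotFoundError(f"no time-series files in {data_dir}/timeseries")
    ts = {s: read_timeseries(data_dir / "timeseries" / f"{s}.tsv") for s in subjects}
    motion = {s: read_motion(data_dir / "motion" / f"{s}.par") for s in subjects}
    return {
        "parcellation": parcellation,
        "behavior": behavior,
        "subjects": subjects,
        "timeseries": ts,
        "motion": motion,
    }


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def qc_stage(subjects, motion, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for sid in subjects:
        fd = framewise_displacement(motion[sid])
        dec = motion_qc(fd, config.mean_fd_max, config.scrub_fd)
        rows.append(
            {
                "subject_id": sid,
                "mean_fd": dec.mean_fd,
                "scrubbed_fraction": dec.scrubbed_fraction,
                "n_scrubbed": dec.n_scrubbed,
                "include": dec.include,
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")


def degree_stage(
    subjects, timeseries, motion, config: PipelineConfig, networks
) -> dict[str, pd.DataFrame]:
    """Clean, correlate and compute degree for the included subjects.

    Confounds are the six motion parameters plus the global signal (mean
    across parcels of the raw series).  Returns subjects x parcels tables
    for total, within- and between-network composite degree.
    """
    total, within, between = {}, {}, {}
    for sid in subjects:
        ts = np.asarray(timeseries[sid], dtype=float)
        fd = framewise_displacement(motion[sid])
        dec = motion_qc(fd, config.mean_fd_max, config.scrub_fd)
        confounds = np.column_stack([motion[sid], ts.mean(axis=1)])
        clean = clean_timeseries(
            ts, confounds=confounds, tr=config.tr, band=config.band
        )
        C = connectivity_matrix(clean, keep_mask=dec.keep_mask)
        total[sid] = composite_degree(C, config.densities)
        w, b = partition_degree(C, networks, config.densities)
        within[sid], between[sid] = w, b
    def table(d):
        return pd.DataFrame.from_dict(d, orient="index").rename_axis("subject_id")
    return {"total": table(total), "within": table(within), "between": table(between)}


def exclusive_significant_parcels(
    res_focus: pd.DataFrame,
    res_other: pd.DataFrame,
    family_alpha: float,
    other_p: float = 0.05,
) -> list:
    """Parcels significantly correlated with behavior in one group only.

    Significant (q < family_alpha) in the focus group and not even
    nominally significant (p >= other_p) in the other group.
    """
    focus = res_focus.index[res_focus["q"] < family_alpha]
    other = res_other.loc[focus, "p"] >= other_p
    return list(focus[other.to_numpy()])


def run_pipeline(
    data: dict | None = None,
    data_dir=None,
    out_dir=None,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full analysis; returns a results dict and writes TSVs.

    ``data`` is the in-memory layout produced by :func:`load_cohort_dir`
    (pass either ``data`` or ``data_dir``).
    """
    config = config or PipelineConfig()
    config.validate()
    if data is None:
        if data_dir is None:
            raise ValueError("pass data or data_dir")
        data = load_cohort_dir(data_dir)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    parcellation = data["parcellation"]
    behavior = data["behavior"]
    subjects = data["subjects"]
    networks = parcellation["network"].to_numpy()
    rng_root = np.random.SeedSequence(config.seed)
    seeds = rng_root.spawn(8)

    # 1. motion QC
    qc = qc_stage(subjects, data["motion"], config)
    included = [s for s in subjects if bool(qc.loc[s, "include"])]
    excluded = sorted(set(subjects) - set(included))
    if excluded:
        logger.info("excluding %d subject(s) for motion: %s", len(excluded), excluded)

    # 2-3. cleaning, connectivity, degree
    degrees = degree_stage(
        included, data["timeseries"], data["motion"], config, networks
    )
    for tab in degrees.values():
        tab.columns = parcellation["parcel_id"]

    behav = behavior.loc[included]
    labels = behav["group"].to_numpy()

    # 4. group permutation test on total composite degree
    group_res = group_permutation_test(
        degrees["total"],
        labels,
        n_perm=config.n_perm_group,
        seed=seeds[0],
        fdr_alpha=config.fdr_alpha,
    )

    # 5. degree-behavior correlations per outcome and sample
    corr_res: dict[tuple[str, str], pd.DataFrame] = {}
    outcomes = ("acc_combined", "rt_combined")
    samples = {
        "all": np.ones(len(included), dtype=bool),
        "control": labels == "control",
        "patient": labels == "patient",
    }
    for oi, outcome in enumerate(outcomes):
        y = behav[outcome].to_numpy(float)
        for si, (name, mask) in enumerate(samples.items()):
            corr_res[(outcome, name)] = correlation_permutation_test(
                degrees["total"][mask],
                y[mask],
                n_perm=config.n_perm_corr,
                seed=seeds[1 + oi].spawn(3)[si],
                family_alpha=config.family_alpha,
                fdr_alpha=config.fdr_alpha,
            )

    # 6. post-hoc within/between decomposition at exclusive parcels
    posthoc_rows = []
    for outcome in outcomes:
        for focus, other in (("patient", "control"), ("control", "patient")):
            parcels = exclusive_significant_parcels(
                corr_res[(outcome, focus)],
                corr_res[(outcome, other)],
                config.family_alpha,
                config.exclusive_other_p,
            )
            mask = samples[focus]
            y = behav.loc[mask, outcome].to_numpy(float)
            for pid in parcels:
                for variant in ("within", "between"):
                    k = degrees[variant].loc[mask, pid].to_numpy(float)
                    if np.std(k) == 0 or np.std(y) == 0:
                        r, p = 0.0, 1.0
                    else:
                        from scipy import stats as _st

                        r, p = _st.pearsonr(k, y)
                    posthoc_rows.append(
                        {
                            "outcome": outcome,
                            "group": focus,
                            "parcel": pid,
                            "variant": variant,
                            "r": r,
                            "p": p,
                            "significant": p < config.posthoc_alpha,
                        }
                    )
    posthoc = pd.DataFrame(
        posthoc_rows,
        columns=[
            "outcome", "group", "parcel", "variant", "r", "p", "significant",
        ],
    )

    # 7. degree-based prediction (whole included sample)
    predictions = {}
    for oi, outcome in enumerate(outcomes):
        y = behav[outcome].to_numpy(float)
        res = cpm_loocv(
            degrees["total"].to_numpy(), y, p_select=config.p_select
        )
        res.permutation_p = cpm_significance(
            degrees["total"].to_numpy(),
            y,
            observed_r=res.r,
            n_perm=config.n_perm_cpm,
            seed=seeds[3 + oi],
            p_select=config.p_select,
        )
        res.n_perm = config.n_perm_cpm
        predictions[outcome] = res

    # 8. behavioral group comparison (Table-1-style block)
    behavioral = {
        "acc": group_compare(behav, "acc", variant=config.ttest_variant),
        "rt": group_compare(behav, "rt", variant=config.ttest_variant),
    }

    results = {
        "config": config,
        "qc": qc,
        "included": included,
        "excluded": excluded,
        "degrees": degrees,
        "group_test": group_res,
        "correlations": corr_res,
        "posthoc": posthoc,
        "predictions": predictions,
        "behavioral": behavioral,
    }
    if out is not None:
        _write_outputs(results, parcellation, behav, out, data_dir)
    return results


def _write_outputs(results, parcellation, behav, out: Path, data_dir) -> None:
    netmap = parcellation.set_index("parcel_id")["network"]
    results["qc"].to_csv(out / "qc_report.tsv", sep="\t")
    deg = results["degrees"]
    deg["total"].to_csv(out / "degree_total.tsv", sep="\t")
    deg["within"].to_csv(out / "degree_within.tsv", sep="\t")
    deg["between"].to_csv(out / "degree_between.tsv", sep="\t")
    gt = results["group_test"].copy()
    gt.insert(0, "network", netmap.reindex(gt.index).to_numpy())
    gt.to_csv(out / "group_test.tsv", sep="\t")
    for (outcome, sample), res in results["correlations"].items():
        res2 = res.copy()
        res2.insert(0, "network", netmap.reindex(res2.index).to_numpy())
        res2.to_csv(out / f"corr_{outcome}_{sample}.tsv", sep="\t")
    results["posthoc"].to_csv(out / "posthoc_within_between.tsv", sep="\t", index=False)
    for outcome, pred in results["predictions"].items():
        pd.DataFrame(
            {
                "subject_id": behav.index,
                "observed": pred.observed,
                "predicted": pred.predicted,
                "score": pred.scores,
            }
        ).to_csv(out / f"prediction_{outcome}.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "parcel_id": parcellation["parcel_id"],
                "network": parcellation["network"],
                "prevalence": pred.prevalence,
            }
        ).to_csv(out / f"prevalence_{outcome}.tsv", sep="\t", index=False)
        (out / f"prediction_{outcome}.json").write_text(
            json.dumps(
                {
                    "r": pred.r,
                    "permutation_p": pred.permutation_p,
                    "p_select": pred.p_select,
                    "n_perm": pred.n_perm,
                    "seed": results["config"].seed,
                },
                indent=2,
            )
        )
    for name, tab in results["behavioral"].items():
        tab.to_csv(out / f"behavioral_{name}.tsv", sep="\t")
    checksums = {}
    if data_dir is not None:
        for p in sorted(Path(data_dir).rglob("*")):
            if p.is_file():
                checksums[str(p.relative_to(data_dir))] = _checksum(p)
    provenance = {
        "package": f"hubdegree {__version__}",
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": dataclasses.asdict(results["config"]),
        "seed": results["config"].seed,
        "included": results["included"],
        "excluded": results["excluded"],
        "input_checksums": checksums,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=list))
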