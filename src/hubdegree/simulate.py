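"""Synthetic multi-subject cohorts with planted network structure.

The generator emulates the statistical structure the degree analysis
assumes, without any image-level realism:

* a parcellation assigning each parcel to one of the standard cortical
  network communities (default-mode, attention, frontoparietal, ... plus an
  "unassigned" class), by default 333 parcels over 13 labels;
* per-subject parcel time series drawn from a zero-mean multivariate normal
  with block covariance — a common within-network correlation, a weaker
  between-network correlation, designated hub parcels with boosted
  correlations to the whole cortex, and a per-group additive offset on the
  hub correlations (the planted group effect);
* six-parameter motion traces as bounded random walks with occasional
  translation spikes that exceed the scrubbing threshold;
* behavioral records whose combined working-memory accuracy is linearly
  coupled to the mean composite degree at designated parcels, with Gaussian
  noise, plus per-load values scattered around the combined score and
  reaction times with a group offset.

All randomness flows from one top-level seed through
``numpy.random.SeedSequence.spawn``, so identical (config, seed) pairs give
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .connectivity import SCRUB_FD
from .degree import DEFAULT_DENSITIES, composite_degree

__all__ = [
    "NETWORK_LABELS",
    "DEFAULT_NETWORK_SIZES",
    "CohortModel",
    "Cohort",
    "make_parcellation",
    "block_covariance",
    "simulate_subject",
    "simulate_cohort",
    "attach_behavior",
    "calibrate_behavior_noise",
]

#: Network community vocabulary (12 networks plus the unassigned class).
NETWORK_LABELS = (
    "DMN", "VAN", "DAN", "FPN", "CON", "SM", "SML",
    "VN", "AN", "SN", "CP", "RSP", "UA",
)

#: Community sizes for the default 333-parcel parcellation.
DEFAULT_NETWORK_SIZES: dict[str, int] = {
    "DMN": 41, "SM": 38, "SML": 8, "VN": 39, "FPN": 24, "AN": 24,
    "CP": 5, "RSP": 8, "CON": 40, "VAN": 23, "SN": 4, "DAN": 32, "UA": 47,
}

WM_LOADS = (1, 3, 5, 7)


def make_parcellation(
    n_parcels: int | None = None,
    network_sizes: dict[str, int] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Build a parcel table with network assignments and random centroids.

    Parcels are numbered 1..n and assigned contiguously to the networks in
    the order given.  Centroids are uniform in a 140 mm box and exist only
    so downstream tables have coordinates to carry.
    """
    if network_sizes is None:
        network_sizes = dict(DEFAULT_NETWORK_SIZES)
    total = sum(network_sizes.values())
    if n_parcels is None:
        n_parcels = total
    if total != n_parcels:
        raise ValueError(
            f"network sizes sum to {total} but n_parcels is {n_parcels}"
        )
    if n_parcels < 2:
        raise ValueError("need at least 2 parcels")
    networks = [
        net for net, size in network_sizes.items() for _ in range(size)
    ]
    rng = np.random.default_rng(seed)
    xyz = rng.uniform(-70, 70, size=(n_parcels, 3)).round(1)
    return pd.DataFrame(
        {
            "parcel_id": np.arange(1, n_parcels + 1),
            "parcel_label": [
                f"{net}_{i}" for i, net in enumerate(networks, start=1)
            ],
            "network": networks,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
        }
    )


@dataclass
class CohortModel:
    """Generating model for a two-group synthetic cohort.

    The defaults emulate the study conditions the analysis targets: 29
    patients and 29 controls, a 333-parcel / 13-community parcellation,
    6 minutes of scanning at TR = 3 s (120 volumes), and Table-1-like
    behavioral summaries (control accuracy ~91.5%, patients ~7 points
    lower; control RT ~880 ms, patients ~70 ms slower).
    """

    n_controls: int = 29
    n_patients: int = 29
    network_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_NETWORK_SIZES)
    )
    n_volumes: int = 120
    tr: float = 3.0
    # covariance structure
    rho_within: float = 0.30
    rho_between: float = 0.05
    hub_parcels: tuple[int, ...] = ()      # parcel_ids (1-based)
    rho_hub: float = 0.25
    group_delta: float = 0.0               # added to hub correlations in patients
    # behavior coupling
    coupling_parcels: tuple[int, ...] = ()  # parcel_ids (1-based)
    beta: float = 0.0                       # accuracy % per unit mean degree
    sigma_y: float = 6.0                    # accuracy noise SD (%)
    target_r2: float | None = None          # if set, sigma_y is calibrated to
                                            # this population R^2 at generation
    accuracy_intercept: float = 91.5        # control mean when beta = 0
    patient_accuracy_offset: float = -7.0
    load_offsets: tuple[float, ...] = (6.0, 2.0, -2.0, -6.0)
    load_noise_sd: float = 1.5
    rt_intercept: float = 879.5             # ms, control mean
    patient_rt_offset: float = 70.0
    sigma_rt: float = 135.0
    # motion
    spike_rate: float = 0.01                # per-volume spike probability
    walk_sd_mm: float = 0.03                # translation step SD
    walk_sd_rad: float = 0.0002             # rotation step SD
    densities: tuple[float, ...] = DEFAULT_DENSITIES

    @property
    def n_parcels(self) -> int:
        return sum(self.network_sizes.values())

    def validate(self) -> None:
        if self.n_controls < 2 or self.n_patients < 2:
            raise ValueError("group sizes must be at least 2")
        if self.n_volumes < 10:
            raise ValueError("need at least 10 volumes")
        if not 0 <= self.rho_within < 1:
            raise ValueError("rho_within must lie in [0, 1)")
        if not 0 <= self.rho_between <= self.rho_within:
            raise ValueError("rho_between must lie in [0, rho_within]")
        if not 0 <= self.rho_hub < 1:
            raise ValueError("rho_hub must lie in [0, 1)")
        if not -1 < self.rho_hub + self.group_delta < 1:
            raise ValueError("hub correlation plus group offset leaves (-1, 1)")
        ids = set(range(1, self.n_parcels + 1))
        if not set(self.hub_parcels) <= ids:
            raise ValueError("hub_parcels outside the parcellation")
        if not set(self.coupling_parcels) <= ids:
            raise ValueError("coupling_parcels outside the parcellation")
        if self.beta != 0 and len(self.coupling_parcels) == 0:
            raise ValueError("beta != 0 requires a nonempty coupling set")
        if self.sigma_y < 0 or self.sigma_rt < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.target_r2 is not None and not 0 < self.target_r2 < 1:
            raise ValueError("target_r2 must lie in (0, 1)")


def block_covariance(model: CohortModel, group: str) -> np.ndarray:
    """Target covariance for one subject, repaired to PSD.

    Correlations are ``rho_within`` inside a network block, ``rho_between``
    across blocks, and ``rho_hub`` (plus ``group_delta`` for patients) on
    the rows/columns of hub parcels.  Negative eigenvalues are clipped to
    1e-8 and the matrix re-symmetrized; naive block constructions with hub
    boosts can be indefinite.
    """
    model.validate()
    n = model.n_parcels
    S = np.full((n, n), model.rho_between)
    start = 0
    for size in model.network_sizes.values():
        S[start : start + size, start : start + size] = model.rho_within
        start += size
    rho_h = model.rho_hub + (model.group_delta if group == "patient" else 0.0)
    hubs = np.asarray(model.hub_parcels, dtype=int) - 1
    if hubs.size:
        S[hubs, :] = rho_h
        S[:, hubs] = rho_h
    np.fill_diagonal(S, 1.0)
    # PSD repair by eigenvalue clipping
    vals, vecs = np.linalg.eigh(S)
    if vals.min() < 1e-8:
        vals = np.clip(vals, 1e-8, None)
        S = (vecs * vals) @ vecs.T
        S = (S + S.T) / 2.0
    return S


def _simulate_motion(model: CohortModel, rng: np.random.Generator) -> np.ndarray:
    """Bounded random walk (AR(1)) with sparse persistent translation jumps."""
    T = model.n_volumes
    steps_rot = rng.normal(0, model.walk_sd_rad, size=(T, 3))
    steps_tr = rng.normal(0, model.walk_sd_mm, size=(T, 3))
    spikes = rng.random(T) < model.spike_rate
    spikes[0] = False
    axis = rng.integers(0, 3, size=T)
    sign = rng.choice([-1.0, 1.0], size=T)
    # a spike is a persistent 0.7 mm repositioning on one translation axis,
    # yielding FD > 0.5 mm at exactly that volume
    for t in np.flatnonzero(spikes):
        steps_tr[t, axis[t]] += sign[t] * (SCRUB_FD + 0.2)
    rot = np.empty((T, 3))
    tr = np.empty((T, 3))
    rot[0] = steps_rot[0]
    tr[0] = steps_tr[0]
    for t in range(1, T):
        rot[t] = 0.95 * rot[t - 1] + steps_rot[t]
        tr[t] = 0.95 * tr[t - 1] + steps_tr[t]
    return np.column_stack([rot, tr])


def simulate_subject(
    model: CohortModel, group: str, seed
) -> tuple[np.ndarray, np.ndarray]:
    """One subject's (time series T x n, motion trace T x 6)."""
    if group not in ("control", "patient"):
        raise ValueError(f"group must be 'control' or 'patient', got {group!r}")
    model.validate()
    rng = np.random.default_rng(seed)
    S = block_covariance(model, group)
    L = np.linalg.cholesky(S + 1e-10 * np.eye(model.n_parcels))
    ts = rng.standard_normal((model.n_volumes, model.n_parcels)) @ L.T
    motion = _simulate_motion(model, rng)
    return ts, motion


def calibrate_behavior_noise(
    coupling_scores, beta: float, target_r2: float
) -> float:
    """Noise SD giving a target population R^2 for the linear coupling.

    With behavior = beta * score + noise, R^2 = beta^2 Var(score) /
    (beta^2 Var(score) + sigma^2); solve for sigma.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must lie in (0, 1)")
    s = float(np.std(np.asarray(coupling_scores, dtype=float), ddof=1))
    return abs(beta) * s * np.sqrt((1 - target_r2) / target_r2)


def attach_behavior(
    degrees: pd.DataFrame,
    groups,
    model: CohortModel,
    seed,
) -> pd.DataFrame:
    """Behavioral records coupled to composite degree.

    ``degrees`` is a subjects x parcels table (columns are parcel_ids).
    Combined accuracy = intercept + beta * (mean degree over the coupling
    parcels, centered across subjects) + group offset + N(0, sigma_y); the
    score is centered so the intercept remains the group mean regardless of
    the degree scale, keeping accuracies inside [0, 100].  Per-load
    accuracies scatter around the combined value with fixed load offsets
    (easier loads more accurate) and the combined column is their exact
    mean.  Reaction times carry the group offset and noise only.
    """
    model.validate()
    groups = np.asarray(groups)
    n = len(degrees)
    if groups.shape[0] != n:
        raise ValueError("groups length does not match degree table")
    rng = np.random.default_rng(seed)
    if model.beta != 0:
        cols = [c for c in degrees.columns if int(c) in set(model.coupling_parcels)]
        if len(cols) != len(model.coupling_parcels):
            raise ValueError("coupling parcels missing from degree table")
        score = degrees[cols].to_numpy().mean(axis=1)
        score = score - score.mean()
    else:
        score = np.zeros(n)
    sigma_y = model.sigma_y
    if model.target_r2 is not None and model.beta != 0:
        sigma_y = calibrate_behavior_noise(score, model.beta, model.target_r2)
    is_patient = groups == "patient"
    acc = (
        model.accuracy_intercept
        + model.beta * score
        + np.where(is_patient, model.patient_accuracy_offset, 0.0)
        + rng.normal(0, sigma_y, size=n)
    )
    offsets = np.asarray(model.load_offsets)
    per_load = (
        acc[:, None]
        + offsets[None, :]
        + rng.normal(0, model.load_noise_sd, size=(n, len(WM_LOADS)))
    )
    per_load = np.clip(per_load, 0.0, 100.0)
    rt = (
        model.rt_intercept
        + np.where(is_patient, model.patient_rt_offset, 0.0)
        + rng.normal(0, model.sigma_rt, size=n)
    )
    rt_load = np.clip(
        rt[:, None] + rng.normal(0, 25.0, size=(n, len(WM_LOADS))), 1.0, None
    )
    out = pd.DataFrame(
        {
            "subject_id": degrees.index,
            "group": groups,
        }
    )
    for j, load in enumerate(WM_LOADS):
        out[f"acc_{load}"] = per_load[:, j]
    for j, load in enumerate(WM_LOADS):
        out[f"rt_{load}"] = rt_load[:, j]
    out["acc_combined"] = per_load.mean(axis=1)
    out["rt_combined"] = rt_load.mean(axis=1)
    return out


def study_model(**overrides) -> CohortModel:
    """The default study-conditions cohort model.

    29 patients and 29 controls, 333 parcels / 13 communities, 120 volumes
    at TR = 3 s, six hub parcels spread over the major communities with a
    patient-side hub-correlation offset of 0.05 (producing medium-to-large
    standardized group differences in composite degree at the planted
    hubs), and combined accuracy coupled to mean composite degree at three
    ventral-attention parcels at a true R^2 of 0.25.
    """
    params = dict(
        hub_parcels=(10, 60, 130, 200, 235, 300),
        group_delta=0.05,
        coupling_parcels=(228, 240, 245),
        beta=0.2,
        target_r2=0.25,
    )
    params.update(overrides)
    return CohortModel(**params)


@dataclass
class Cohort:
    """A simulated cohort: parcellation, per-subject data, behavior."""

    parcellation: pd.DataFrame
    subjects: list[str]
    groups: dict[str, str]
    timeseries: dict[str, np.ndarray]
    motion: dict[str, np.ndarray]
    behavior: pd.DataFrame
    degrees: pd.DataFrame
    model: CohortModel
    seed: int

    def config(self) -> dict:
        cfg = asdict(self.model)
        cfg["seed"] = self.seed
        return cfg


def simulate_cohort(model: CohortModel, seed: int) -> Cohort:
    """Generate a full cohort and couple behavior to realized degree.

    Behavior is attached to each subject's composite degree as the analysis
    measures it — confound regression (six motion parameters plus global
    signal), 0.01–0.08 Hz band-pass, scrubbing at FD > 0.5 mm, Fisher-z
    connectivity, default density sweep — so the planted degree–behavior
    relation is expressed on the same scale the pipeline estimates.
    """
    from .connectivity import (
        clean_timeseries,
        connectivity_matrix,
        framewise_displacement,
        motion_qc,
    )

    model.validate()
    root = np.random.SeedSequence(seed)
    n_total = model.n_controls + model.n_patients
    seeds = root.spawn(n_total + 1)
    parcellation = make_parcellation(
        network_sizes=model.network_sizes, seed=seed
    )
    subjects, groups, ts_map, mot_map = [], {}, {}, {}
    deg_rows = []
    idx = 0
    for group, count in (
        ("control", model.n_controls),
        ("patient", model.n_patients),
    ):
        for i in range(count):
            sid = f"{'ctl' if group == 'control' else 'pat'}{i + 1:03d}"
            ts, motion = simulate_subject(model, group, seeds[idx])
            subjects.append(sid)
            groups[sid] = group
            ts_map[sid] = ts
            mot_map[sid] = motion
            confounds = np.column_stack([motion, ts.mean(axis=1)])
            clean = clean_timeseries(ts, confounds=confounds, tr=model.tr)
            keep = motion_qc(framewise_displacement(motion)).keep_mask
            deg_rows.append(
                composite_degree(
                    connectivity_matrix(clean, keep_mask=keep), model.densities
                )
            )
            idx += 1
    degrees = pd.DataFrame(
        deg_rows,
        index=pd.Index(subjects, name="subject_id"),
        columns=parcellation["parcel_id"],
    )
    behavior = attach_behavior(
        degrees, [groups[s] for s in subjects], model, seeds[n_total]
    )
    return Cohort(
        parcellation=parcellation,
        subjects=subjects,
        groups=groups,
        timeseries=ts_map,
        motion=mot_map,
        behavior=behavior,
        degrees=degrees,
        model=model,
        seed=seed,
    )
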