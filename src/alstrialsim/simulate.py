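"""Assembly of complete two-arm trial datasets.

A trial couples the disease model to a design: 1:1 allocation, monthly
visits with small Normal jitter, observation noise on the ALSFRS-R,
non-informative dropout, and administrative censoring at the follow-up
horizon.  Death truncates the longitudinal series — the informative
missingness the analysis strategies must confront.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import disease
from .params import JointModelParameters, TrialDesign

__all__ = [
    "TrialDataset",
    "generate_visit_schedule",
    "generate_trial",
    "write_trial",
    "read_trial",
]

LONG_COLUMNS = ["subject_id", "arm", "time_months", "alsfrs_r"]
SURV_COLUMNS = ["subject_id", "arm", "time_months", "status"]


@dataclass
class TrialDataset:
    """Long-format longitudinal records plus per-subject survival records.

    ``longitudinal`` has columns subject_id, arm, time_months, alsfrs_r
    (and an internal ``visit_index`` giving the scheduled-visit number);
    ``survival`` has subject_id, arm, time_months, status (1 = death).
    """

    longitudinal: pd.DataFrame
    survival: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.survival)

    def validate(self) -> None:
        long, surv = self.longitudinal, self.survival
        for col in LONG_COLUMNS:
            if col not in long.columns:
                raise ValueError(f"longitudinal table missing column {col!r}")
        for col in SURV_COLUMNS:
            if col not in surv.columns:
                raise ValueError(f"survival table missing column {col!r}")
        if surv.subject_id.duplicated().any():
            raise ValueError("duplicate subject_id in survival table")
        if (surv.time_months < 0).any() or (long.time_months < 0).any():
            raise ValueError("negative times")
        if not set(surv.status.unique()) <= {0, 1}:
            raise ValueError("status must be 0/1")
        fu = surv.set_index("subject_id").time_months
        g = long.groupby("subject_id").time_months
        if not long.subject_id.isin(fu.index).all():
            bad = long.loc[~long.subject_id.isin(fu.index), "subject_id"].unique()
            raise ValueError(f"longitudinal subjects missing from survival table: {bad[:5]}")
        last = g.max()
        over = last[last > fu.loc[last.index] + 1e-9]
        if len(over):
            raise ValueError(
                f"longitudinal time exceeds follow-up for subjects {list(over.index[:5])}"
            )
        first = g.min()
        if (first > 1e-9).any():
            raise ValueError("every subject requires a baseline visit at t=0")
        if (g.apply(lambda s: (np.diff(s.to_numpy()) <= 0).any())).any():
            raise ValueError("per-subject visit times must be strictly increasing")

    def visit_matrices(self):
        """Observed scores and visit times on the scheduled-visit grid.

        Returns ``(scores, times)``: two (n_subjects, n_visits) arrays,
        NaN where unobserved, rows ordered like ``survival.subject_id``
        and columns indexed by the scheduled visit number (nearest nominal
        month when the data were read from file).
        """
        long = self.longitudinal
        if "visit_index" in long.columns:
            vidx = long.visit_index.to_numpy(int)
        else:
            vidx = np.rint(long.time_months.to_numpy()).astype(int)
        n_vis = vidx.max() + 1
        order = {sid: k for k, sid in enumerate(self.survival.subject_id)}
        rows = long.subject_id.map(order).to_numpy()
        scores = np.full((len(order), n_vis), np.nan)
        times = np.full((len(order), n_vis), np.nan)
        scores[rows, vidx] = long.alsfrs_r.to_numpy()
        times[rows, vidx] = long.time_months.to_numpy()
        return scores, times

    def score_matrix(self):
        """Observed ALSFRS-R on the scheduled-visit grid (NaN = unobserved)."""
        return self.visit_matrices()[0]


def generate_visit_schedule(design: TrialDesign, rng: np.random.Generator) -> np.ndarray:
    """One subject's visit times: nominal grid plus Normal jitter.

    Baseline is fixed at exactly 0; each later nominal time gets
    independent Normal(0, jitter_sd^2) noise, redrawn (not truncated) if
    the jittered time falls below zero, so the marginal jitter SD is
    preserved.  The result is sorted ascending.
    """
    nominal = np.arange(0.0, design.max_followup + 1e-9, design.visit_interval)
    times = nominal.copy()
    if design.visit_jitter_sd > 0 and len(nominal) > 1:
        jit = rng.normal(0.0, design.visit_jitter_sd, size=len(nominal) - 1)
        t = nominal[1:] + jit
        bad = t < 0
        while bad.any():
            t[bad] = nominal[1:][bad] + rng.normal(
                0.0, design.visit_jitter_sd, size=int(bad.sum()))
            bad = t < 0
        times[1:] = t
    return np.sort(times)


def _params_hash(params: JointModelParameters) -> str:
    raw = repr([
        params.beta0, params.beta1, params.slope_reduction, params.gamma,
        params.alpha, params.re_cov.tolist(), params.sigma_res,
        params.weibull_shape, params.weibull_scale, params.clamp_trajectory,
    ]).encode()
    return hashlib.sha256(raw).hexdigest()[:12]


def generate_trial(params: JointModelParameters, design: TrialDesign,
                   rng: np.random.Generator | int | None = None) -> TrialDataset:
    """Simulate a complete two-arm trial.

    Per subject: random effects b ~ MVN(0, re_cov); death time by
    inverse-transform from the conditional hazard; an independent
    Bernoulli(dropout_fraction) dropout at Uniform(0, max_followup);
    follow-up = min(death, dropout, horizon); noisy ALSFRS-R observations
    at every scheduled visit up to follow-up.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(design.seed if rng is None else rng)
    n = design.n_per_arm
    N = 2 * n
    arm = np.repeat([0.0, 1.0], n)
    b = rng.standard_normal((N, 3)) @ params.re_chol().T
    u = rng.uniform(size=N)
    # u=0/1 occur with probability 0 but would break the inverse transform
    u = np.clip(u, 1e-12, 1 - 1e-12)
    death_t, death_obs = disease.sample_event_times(params, b, arm, u,
                                                    design.max_followup)
    drop = rng.uniform(size=N) < design.dropout_fraction
    drop_t = np.where(drop, rng.uniform(0.0, design.max_followup, size=N), np.inf)
    eff_death = np.where(death_obs, death_t, np.inf)
    follow = np.minimum.reduce([eff_death, drop_t,
                                np.full(N, float(design.max_followup))])
    status = (eff_death <= np.minimum(drop_t, design.max_followup)).astype(int)

    sids, arms, times, scores, vindex = [], [], [], [], []
    subj_ids = np.arange(N)
    for i in subj_ids:
        sched = generate_visit_schedule(design, rng)
        keep = sched <= follow[i] + 1e-12
        idx = np.nonzero(keep)[0]
        t = sched[idx]
        latent = disease.trajectory_value(params, b[i], arm[i], t)
        y = latent + rng.normal(0.0, params.sigma_res, size=len(t))
        sids.append(np.full(len(t), i))
        arms.append(np.full(len(t), arm[i]))
        times.append(t)
        scores.append(y)
        vindex.append(idx)
    long = pd.DataFrame({
        "subject_id": np.concatenate(sids).astype(int),
        "arm": np.concatenate(arms).astype(int),
        "time_months": np.concatenate(times),
        "alsfrs_r": np.concatenate(scores),
        "visit_index": np.concatenate(vindex).astype(int),
    })
    surv = pd.DataFrame({
        "subject_id": subj_ids,
        "arm": arm.astype(int),
        "time_months": follow,
        "status": status,
    })
    assert (long.groupby("subject_id").size().reindex(subj_ids).fillna(0) > 0).all(), \
        "every subject must have a baseline visit"
    ds = TrialDataset(long, surv, provenance={
        "seed": design.seed, "params_hash": _params_hash(params),
    })
    return ds


def write_trial(dataset: TrialDataset, prefix) -> tuple[str, str]:
    """Write ``<prefix>_longitudinal.csv`` and ``<prefix>_survival.csv``.

    A provenance comment header (seed, parameter hash) precedes the CSV
    header; the round-trip through :func:`read_trial` is lossless.
    """
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    header = "".join(
        f"# {k}: {v}\n" for k, v in dataset.provenance.items()
    )
    paths = []
    for tag, df, cols in (
        ("longitudinal", dataset.longitudinal, LONG_COLUMNS),
        ("survival", dataset.survival, SURV_COLUMNS),
    ):
        path = prefix.parent / f"{prefix.name}_{tag}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            df[cols].to_csv(fh, index=False)
        paths.append(str(path))
    return tuple(paths)


def read_trial(long_path, surv_path) -> TrialDataset:
    """Read and validate a trial written by :func:`write_trial`."""
    def _read(path, cols):
        df = pd.read_csv(path, comment="#")
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}")
        return df

    long = _read(long_path, LONG_COLUMNS)
    surv = _read(surv_path, SURV_COLUMNS)
    long = long.sort_values(["subject_id", "time_months"], kind="stable",
                            ignore_index=True)
    long["visit_index"] = np.rint(long.time_months.to_numpy()).astype(int)
    ds = TrialDataset(long, surv.reset_index(drop=True))
    ds.validate()
    return ds
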