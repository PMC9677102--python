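"""Synthetic-cohort generator for the three-state weight-status pipeline.

The generator emulates the structure of an annual school-examination
cohort: ~2,334 children first seen around age 6.8, followed for six yearly
waves, with latent weight-status trajectories evolving as a continuous-time
Markov chain on (normal, overweight, obese) with adjacent-only jumps.
Latent paths are simulated exactly (Gillespie: exponential holding times
with rate -q_rr, jump to s with probability q_rs / -q_rr) and observed only
at wave times, reproducing the interval censoring of panel data.

Observed anthropometry is built *state-consistently*: the latent state at
each wave is drawn first, and the child's BMI is then placed inside that
state's band of the chosen cutoff table while tracking a smooth child-level
quadratic BMI curve with a nadir (the adiposity rebound).  This guarantees
that re-classifying the generated BMIs with the same table reproduces the
generated states exactly — a deliberate simplification of reality, see the
methods note.  Heights follow child-level linear growth; weights are backed
out from BMI and height.

Every draw flows from one seeded generator, so a config (with its seed)
reproduces the cohort byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference
from .classify import CutoffTable, bundled_cutoffs
from .cohort import CohortDataset
from .markov import ADJACENT_MASK, fit, mask_transitions, validate_q

_BAND_MARGIN = 0.05     # kg/m² kept clear of a cutoff when placing BMI in a band
_BAND_BELOW = 5.0       # width of the normal-weight band below c_ow
_BAND_ABOVE = 8.0       # width of the obese band above c_ob


@dataclass
class SimulationConfig:
    """Study-structure and generating-truth parameters.

    Defaults mirror the emulated cohort: 2,334 children, six annual waves
    from about age 6.8, baseline state distribution (0.711, 0.181, 0.108),
    49.7% girls, 78.9% urban schools, and the bundled reference intensity
    matrix as the generating truth.
    """

    n_children: int = reference.N_CHILDREN
    n_waves: int = reference.N_WAVES
    wave_spacing: float = 1.0
    spacing_jitter: float = 0.0          # +-years, uniform; exercises unequal intervals
    start_age_mean: float = 6.8
    start_age_sd: float = 0.15
    q: np.ndarray = field(default_factory=lambda: reference.REFERENCE_INTENSITIES["all"].copy())
    covariate_effects: dict[str, np.ndarray] = field(default_factory=dict)
    #: P(girl); the emulated cohort is 49.7% girls.
    sex_ratio_girls: float = 0.497
    urban_share: float = 0.789
    initial_state_dist: np.ndarray = field(
        default_factory=lambda: reference.BASELINE_STATE_DISTRIBUTION["all"].copy()
    )
    # BMI-curve truth: nadir ~ N(mean, sd) years, curvature kg/m²/y²,
    # per-wave BMI noise kg/m² (within-band).
    nadir_age_mean: float = 6.7
    nadir_age_sd: float = 1.0
    bmi_at_nadir_mean: float = 15.3
    bmi_at_nadir_sd: float = 1.0
    curvature_mean: float = 0.20
    curvature_sd: float = 0.04
    bmi_noise_sd: float = 0.3
    cutoffs: CutoffTable | None = None   # default: bundled who_style fixture
    seed: int = 0

    def validate(self) -> None:
        validate_q(self.q)
        if np.count_nonzero(np.triu(self.q, 2)) or np.count_nonzero(np.tril(self.q, -2)):
            raise ValueError("generating Q must be tridiagonal (adjacent transitions only)")
        p = np.asarray(self.initial_state_dist, float)
        if p.shape != (3,) or abs(p.sum() - 1.0) > 1e-8 or (p < 0).any():
            raise ValueError("initial state distribution must be a 3-probability vector")
        if self.wave_spacing <= 0 or self.n_waves < 2 or self.n_children < 1:
            raise ValueError("need positive spacing, >=2 waves, >=1 child")
        if self.spacing_jitter < 0 or self.spacing_jitter >= self.wave_spacing / 2:
            raise ValueError("spacing jitter must be in [0, spacing/2)")
        for name, b in self.covariate_effects.items():
            if np.asarray(b, float).shape != (len(mask_transitions(ADJACENT_MASK)),):
                raise ValueError(f"covariate effect {name!r} needs one log-HR per transition")
        if not 0 <= self.sex_ratio_girls <= 1 or not 0 <= self.urban_share <= 1:
            raise ValueError("sex ratio and urban share must be probabilities")


def simulate_trajectory(
    Q: np.ndarray, start_state: int, horizon: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Exact event-time path of the chain over [0, horizon].

    Returns (jump_times, states): ``states[i]`` is occupied from
    ``jump_times[i]`` until ``jump_times[i+1]`` (or the horizon); the first
    entry is (0, start_state).
    """
    Q = validate_q(Q)
    times = [0.0]
    states = [int(start_state)]
    t, s = 0.0, int(start_state)
    while True:
        rate = -Q[s - 1, s - 1]
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= horizon:
            break
        probs = Q[s - 1].copy()
        probs[s - 1] = 0.0
        probs = probs / rate
        s = int(rng.choice(3, p=probs)) + 1
        times.append(t)
        states.append(s)
    return np.array(times), np.array(states)


def states_at(jump_times: np.ndarray, states: np.ndarray, query: np.ndarray) -> np.ndarray:
    """State occupied at each query time (panel observation of a path)."""
    idx = np.searchsorted(jump_times, query, side="right") - 1
    return states[idx]


def _child_q(cfg: SimulationConfig, z: dict[str, float]) -> np.ndarray:
    """Per-child intensity matrix: baseline rates scaled by exp(beta . z)."""
    Q = cfg.q.copy()
    if cfg.covariate_effects:
        trans = mask_transitions(ADJACENT_MASK)
        scale = np.zeros(len(trans))
        for name, beta in cfg.covariate_effects.items():
            scale = scale + np.asarray(beta, float) * z[name]
        for (r, s), f in zip(trans, np.exp(scale)):
            Q[r, s] = Q[r, s] * f
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _bmi_in_band(
    curve_val: float, state: int, c_ow: float, c_ob: float, noise: float
) -> float:
    """Place a BMI near the child's curve but inside the state's band."""
    lo, hi = {
        1: (c_ow - _BAND_BELOW, c_ow - _BAND_MARGIN),
        # lower edges sit 0.01 above the cutoff so that rounding weight to
        # 0.01 kg cannot push the recomputed BMI across the boundary
        2: (c_ow + 0.01, c_ob - _BAND_MARGIN),
        3: (c_ob + 0.01, c_ob + _BAND_ABOVE),
    }[state]
    return float(np.clip(curve_val + noise, lo, hi))


def generate_cohort(cfg: SimulationConfig) -> tuple[CohortDataset, dict]:
    """Simulate a full panel cohort plus a truth record for recovery tests.

    Returns
    -------
    (dataset, truth)
        ``dataset`` carries the same columns :func:`weightstates.cohort.load_panel`
        produces (plus ``state`` and numeric ``male`` / ``semi_urban``
        covariates).  ``truth`` holds the generating Q, covariate log-HRs,
        per-child latent paths, nadir ages and late-AR flags.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    table = cfg.cutoffs if cfg.cutoffs is not None else bundled_cutoffs("who_style")

    n = cfg.n_children
    sex = np.where(rng.random(n) < cfg.sex_ratio_girls, "girl", "boy")
    area = np.where(rng.random(n) < cfg.urban_share, "urban", "semi-urban")
    start_age = np.clip(
        rng.normal(cfg.start_age_mean, cfg.start_age_sd, n),
        cfg.start_age_mean - 0.5,
        cfg.start_age_mean + 0.5,
    )
    start_state = rng.choice(3, size=n, p=np.asarray(cfg.initial_state_dist, float)) + 1

    nadir = rng.normal(cfg.nadir_age_mean, cfg.nadir_age_sd, n)
    bmi_at_nadir = rng.normal(cfg.bmi_at_nadir_mean, cfg.bmi_at_nadir_sd, n)
    curvature = np.clip(rng.normal(cfg.curvature_mean, cfg.curvature_sd, n), 0.05, None)
    height6 = rng.normal(116.5, 4.8, n)
    growth_rate = np.clip(rng.normal(5.7, 0.6, n), 3.5, None)

    horizon = (cfg.n_waves - 1) * cfg.wave_spacing + 2 * cfg.spacing_jitter + 1e-9

    rows = []
    paths: dict[str, tuple[list[float], list[int]]] = {}
    true_jumps = np.zeros(n, dtype=int)
    for i in range(n):
        cid = f"c{i:05d}"
        z = {"male": float(sex[i] == "boy"), "semi_urban": float(area[i] == "semi-urban")}
        Qi = _child_q(cfg, z)
        jt, js = simulate_trajectory(Qi, start_state[i], horizon, rng)
        paths[cid] = (jt.tolist(), js.tolist())
        true_jumps[i] = len(js) - 1

        offsets = np.arange(cfg.n_waves) * cfg.wave_spacing
        if cfg.spacing_jitter > 0:
            jit = rng.uniform(-cfg.spacing_jitter, cfg.spacing_jitter, cfg.n_waves)
            jit[0] = 0.0
            offsets = offsets + jit
        obs_states = states_at(jt, js, offsets)
        ages = start_age[i] + offsets
        hts = height6[i] + growth_rate[i] * (ages - 6.0) + rng.normal(0, 0.3, cfg.n_waves)
        for w in range(cfg.n_waves):
            c_ow, c_ob = table.lookup(sex[i], ages[w])
            curve_val = bmi_at_nadir[i] + curvature[i] * (ages[w] - nadir[i]) ** 2
            bmi = _bmi_in_band(
                curve_val, int(obs_states[w]), c_ow, c_ob, rng.normal(0, cfg.bmi_noise_sd)
            )
            ht = round(hts[w], 1)  # stadiometer precision, 0.1 cm
            wt = round(bmi * (ht / 100.0) ** 2, 2)  # scale precision, 0.01 kg
            rows.append((cid, sex[i], area[i], ages[w], ht, wt, int(obs_states[w])))

    df = pd.DataFrame(
        rows, columns=["child_id", "sex", "area", "exam_age", "height", "weight", "state"]
    )
    df["t"] = df["exam_age"] - df.groupby("child_id")["exam_age"].transform("first")
    df["bmi"] = df["weight"] / (df["height"] / 100.0) ** 2
    df["initial_bmi"] = df.groupby("child_id")["bmi"].transform("first")
    df["male"] = (df["sex"] == "boy").astype(int)
    df["semi_urban"] = (df["area"] == "semi-urban").astype(int)

    truth = {
        "q": cfg.q.copy(),
        "covariate_effects": {k: np.asarray(v, float) for k, v in cfg.covariate_effects.items()},
        "paths": paths,
        "nadir_age": dict(zip(df["child_id"].unique(), nadir)),
        "late_ar": dict(zip(df["child_id"].unique(), (nadir >= 7.0))),
        "n_true_jumps": dict(zip(df["child_id"].unique(), true_jumps)),
        "cutoff_provenance": table.provenance,
        "seed": cfg.seed,
    }
    return CohortDataset(df=df), truth


def simulate_bmi_panel(
    n_children: int,
    ages: np.ndarray,
    nadir_age_mean: float = 5.5,
    nadir_age_sd: float = 1.0,
    bmi_at_nadir_mean: float = 15.3,
    bmi_at_nadir_sd: float = 1.0,
    curvature_mean: float = 0.20,
    curvature_sd: float = 0.04,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pure quadratic BMI curves without state-band constraints.

    For rebound-estimation studies: each child gets a convex quadratic
    BMI(age) with a random nadir, observed at ``ages`` with i.i.d. noise.
    Returns the long-format panel and the true nadir ages.
    """
    rng = np.random.default_rng(seed)
    ages = np.asarray(ages, float)
    nadir = rng.normal(nadir_age_mean, nadir_age_sd, n_children)
    base = rng.normal(bmi_at_nadir_mean, bmi_at_nadir_sd, n_children)
    curv = np.clip(rng.normal(curvature_mean, curvature_sd, n_children), 0.05, None)
    rows = []
    for i in range(n_children):
        bmi = base[i] + curv[i] * (ages - nadir[i]) ** 2 + rng.normal(0, noise_sd, ages.size)
        for a, b in zip(ages, bmi):
            rows.append((f"c{i:05d}", float(a), float(b)))
    return pd.DataFrame(rows, columns=["child_id", "exam_age", "bmi"]), nadir


def recovery_experiment(
    cfg: SimulationConfig, n_reps: int, seed: int = 0
) -> pd.DataFrame:
    """Bias, RMSE and Wald-CI coverage of the intensity MLEs over replicates.

    Each replicate simulates a fresh cohort from ``cfg`` (reseeded from
    ``seed``), refits the null model and checks each true intensity against
    the replicate's Wald 95% CI.  Non-convergent replicates are recorded and
    skipped, not fatal.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    ss = np.random.SeedSequence(seed)
    trans = mask_transitions(ADJACENT_MASK)
    true_q = np.array([cfg.q[r, s] for r, s in trans])
    est = np.full((n_reps, len(trans)), np.nan)
    covered = np.zeros((n_reps, len(trans)), dtype=bool)
    failures = 0
    for rep, child_seed in enumerate(ss.spawn(n_reps)):
        rep_cfg = replace(cfg, seed=int(child_seed.generate_state(1)[0] % (2**31)))
        ds, _ = generate_cohort(rep_cfg)
        try:
            fm = fit(ds)
        except RuntimeError:
            failures += 1
            continue
        tab = fm.intensity_table()
        est[rep] = tab["q"].to_numpy()
        covered[rep] = (tab["lo"].to_numpy() <= true_q) & (true_q <= tab["hi"].to_numpy())
    ok = ~np.isnan(est[:, 0])
    out = pd.DataFrame(
        {
            "transition": [f"{r + 1}->{s + 1}" for r, s in trans],
            "true_q": true_q,
            "mean_estimate": est[ok].mean(axis=0),
            "bias": est[ok].mean(axis=0) - true_q,
            "rmse": np.sqrt(((est[ok] - true_q) ** 2).mean(axis=0)),
            "coverage": covered[ok].mean(axis=0),
        }
    )
    out.attrs["n_converged"] = int(ok.sum())
    out.attrs["n_failed"] = failures
    return out
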