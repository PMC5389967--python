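"""Simulation-based composite-likelihood fitting of the demographic model.

The observed data are a joint derived-allele frequency spectrum of unlinked
SNPs.  For candidate parameter values the expected entry probabilities of the
polymorphic joint SFS are estimated by coalescent simulation (branch-length
weighting, see :func:`mei_popgen.coalescent_sim.expected_joint_sfs`) and the
composite log-likelihood sum(obs * log p) is maximized by a cycled
stochastic local search over log-transformed parameters, re-simulating the
expectation with a growing budget each cycle.  Confidence intervals come from
a parametric bootstrap (refits of pseudo-observed datasets simulated under
the best model) and goodness-of-fit is assessed by projecting the observed
spectrum into the PCA space of spectra simulated from the CI ranges.

The search is deliberately generic: the caller supplies a ``builder`` mapping
a dict of free parameter values to a DemographicModel, so the same machinery
fits the full 8-parameter model (split time fixed) or reduced models used in
recovery experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .variant_io import ValidationError
from .popgen_stats import JointSFS
from . import coalescent_sim as cs

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitSchedule:
    """Search schedule: cycles of re-simulation with a linearly growing
    simulation budget, restarted from ``replicates`` random initial points."""

    cycles: int = 10
    sims_start: int = 2_000
    sims_end: int = 10_000
    replicates: int = 10

    def validate(self):
        if min(self.cycles, self.sims_start, self.sims_end, self.replicates) < 1:
            raise ValidationError("schedule values must be positive")

    def sims_at(self, cycle: int) -> int:
        if self.cycles == 1:
            return self.sims_end
        f = cycle / (self.cycles - 1)
        return int(round(self.sims_start + f * (self.sims_end - self.sims_start)))


#: the published estimation schedule (expensive; desk work uses the default)
PAPER_SCHEDULE = FitSchedule(cycles=40, sims_start=50_000, sims_end=250_000,
                             replicates=100)
DESK_SCHEDULE = FitSchedule()


@dataclass
class FitResult:
    ml_params: dict[str, float]
    ml_model: "cs.DemographicModel"
    log_cl: float
    replicate_results: list[dict] = field(default_factory=list)
    ci95: dict[str, tuple[float, float]] | None = None
    floored_entries: int = 0
    bound_pinned: list[str] = field(default_factory=list)
    n_refit_failures: int = 0


def composite_log_likelihood(observed: JointSFS | np.ndarray,
                             expected_probs: np.ndarray,
                             floor: float | None = None
                             ) -> tuple[float, int]:
    """sum over polymorphic entries of observed_count * log(expected_prob).

    ``expected_probs`` must be normalized over the polymorphic entries (both
    monomorphic corners zero) — the SNP-conditioned multinomial scheme.
    Zero-probability entries with non-zero observed counts are floored at
    ``floor`` (callers pass 1/(10 * num_simulated_sites)); the number of
    floored entries is returned alongside so degenerate expectations are
    visible, never silent.
    """
    obs = observed.matrix if isinstance(observed, JointSFS) else np.asarray(observed)
    exp = np.asarray(expected_probs, dtype=float)
    if obs.shape != exp.shape:
        raise ValidationError(f"shape mismatch {obs.shape} vs {exp.shape}")
    obs = obs.astype(float).copy()
    obs[0, 0] = 0.0
    obs[-1, -1] = 0.0
    if floor is None:
        floor = 1e-12
    need_floor = (obs > 0) & (exp <= 0)
    n_floored = int(need_floor.sum())
    exp = np.where(need_floor, floor, exp)
    occupied = obs > 0
    return float((obs[occupied] * np.log(exp[occupied])).sum()), n_floored


def _uniform_in_bounds(rng, bounds: dict, log_scale: dict) -> dict:
    out = {}
    for name, (lo, hi) in bounds.items():
        if log_scale[name]:
            out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            out[name] = float(rng.uniform(lo, hi))
    return out


def fit(observed: JointSFS, builder, bounds: dict[str, tuple[float, float]],
        schedule: FitSchedule = DESK_SCHEDULE, seed: int = 1,
        n_candidates: int = 6, init: dict[str, float] | None = None,
        polish_evals: int = 0, polish_sims: int | None = None) -> FitResult:
    """Maximize the composite likelihood of ``observed`` over ``bounds``.

    ``builder(params: dict) -> DemographicModel`` realizes a candidate.  All
    parameters are searched on a log scale (sizes, times and rates are
    positive and span decades).  Each replicate starts from a random point
    (or ``init``), then per cycle proposes ``n_candidates`` log-normal
    perturbations of the incumbent with a step size decaying over cycles,
    evaluates each by re-simulating the expected joint SFS at the cycle's
    simulation budget, and keeps the best scorer; the incumbent is always
    re-evaluated with the same fresh simulations (common random numbers) so
    the comparison is fair.  The best final composite likelihood across
    replicates wins.  With ``polish_evals > 0`` the winner is refined by
    Nelder-Mead in log-parameter space on a common-random-numbers surrogate:
    one simulation seed is frozen so the composite likelihood becomes a
    deterministic function of the parameters, which resolves shallow
    ridge-like directions (joint size/migration rescalings) that per-cycle
    re-simulation noise would otherwise mask.  Estimates near a bound are
    flagged as pinned.  Deterministic given ``seed``.
    """
    schedule.validate()
    if not bounds:
        raise ValidationError("no free parameters")
    for name, (lo, hi) in bounds.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
            raise ValidationError(f"bad bounds for {name}: ({lo}, {hi})")
    n1, n2 = observed.n1 // 2, observed.n2 // 2
    log_scale = {name: True for name in bounds}
    master = np.random.SeedSequence(seed)
    rep_seeds = master.generate_state(schedule.replicates * 2)

    def evaluate(params: dict, n_sims: int, sim_seed: int):
        model = builder(params)
        exp = cs.expected_joint_sfs(model, n1, n2, n_sims, sim_seed)
        cl, n_fl = composite_log_likelihood(observed, exp,
                                            floor=1.0 / (10.0 * n_sims))
        return cl, n_fl

    best_overall = None
    replicate_results = []
    for r in range(schedule.replicates):
        rng = np.random.default_rng(int(rep_seeds[2 * r]))
        current = dict(init) if init is not None and r == 0 else \
            _uniform_in_bounds(rng, bounds, log_scale)
        current_cl, n_fl_total = None, 0
        for cyc in range(schedule.cycles):
            n_sims = schedule.sims_at(cyc)
            step = 0.5 * (0.1 / 0.5) ** (cyc / max(schedule.cycles - 1, 1))
            cands = [current]
            names = list(bounds)
            for j in range(n_candidates):
                cand = dict(current)
                # alternate between coordinate moves (good along soft,
                # ridge-like directions) and joint moves
                move = ([names[int(rng.integers(len(names)))]]
                        if j % 2 == 0 and len(names) > 1 else names)
                for name in move:
                    lo, hi = bounds[name]
                    v = np.log(current[name]) + rng.normal(0, step)
                    cand[name] = float(np.exp(np.clip(v, np.log(lo), np.log(hi))))
                cands.append(cand)
            sim_seed = int(rng.integers(1, 2**31 - 1))
            scores = []
            for cand in cands:
                cl, n_fl = evaluate(cand, n_sims, sim_seed)
                n_fl_total += n_fl
                scores.append(cl)
            ibest = int(np.argmax(scores))
            current, current_cl = cands[ibest], scores[ibest]
        replicate_results.append({"params": current, "log_cl": current_cl,
                                  "floored": n_fl_total})
        if best_overall is None or current_cl > best_overall["log_cl"]:
            best_overall = replicate_results[-1]

    params = best_overall["params"]
    if polish_evals > 0:
        from scipy import optimize

        if polish_sims is None:
            polish_sims = schedule.sims_end
        crn_seed = int(np.random.default_rng(int(rep_seeds[1]))
                       .integers(1, 2**31 - 1))
        names = list(bounds)
        log_lo = np.log([bounds[n][0] for n in names])
        log_hi = np.log([bounds[n][1] for n in names])

        def neg_cl(x):
            p = {n: float(np.exp(v))
                 for n, v in zip(names, np.clip(x, log_lo, log_hi))}
            return -evaluate(p, polish_sims, crn_seed)[0]

        x0 = np.log([params[n] for n in names])
        opt = optimize.minimize(neg_cl, x0, method="Nelder-Mead",
                                options={"maxfev": polish_evals,
                                         "xatol": 0.02, "fatol": 1.0})
        xbest = np.clip(opt.x, log_lo, log_hi)
        params = {n: float(np.exp(v)) for n, v in zip(names, xbest)}
        best_overall = {"params": params, "log_cl": float(-opt.fun),
                        "floored": best_overall["floored"]}
    # a stochastic search rarely sits exactly on a bound; within 2% counts
    pinned = [name for name, (lo, hi) in bounds.items()
              if params[name] <= lo * 1.02 or params[name] >= hi * 0.98]
    if pinned:
        logger.warning("estimates pinned at bounds: %s", pinned)
    return FitResult(ml_params=params, ml_model=builder(params),
                     log_cl=best_overall["log_cl"],
                     replicate_results=replicate_results,
                     floored_entries=best_overall["floored"],
                     bound_pinned=pinned)


def parametric_bootstrap_ci(fit_result: FitResult, builder,
                            bounds: dict[str, tuple[float, float]],
                            n_snps: int, n_datasets: int = 150,
                            n1: int = 7, n2: int = 6,
                            schedule: FitSchedule | None = None,
                            seed: int = 1) -> dict[str, tuple[float, float]]:
    """95% CI by refitting pseudo-observed datasets simulated under the fit.

    Each dataset is a joint SFS of ``n_snps`` unlinked polymorphic sites
    (the same number of SNPs as the original data) simulated under
    ``fit_result.ml_params``; 2.5 / 97.5 percentiles of the refitted values
    are taken per parameter over successful refits.  Failures are counted on
    the fit result, never hidden.
    """
    if n_datasets < 2:
        raise ValidationError("need at least 2 pseudo-datasets")
    if schedule is None:
        schedule = FitSchedule(cycles=4, sims_start=1_000, sims_end=4_000,
                               replicates=2)
    model = fit_result.ml_model
    master = np.random.SeedSequence([seed, 777])
    ds_seeds = master.generate_state(n_datasets)
    estimates: dict[str, list[float]] = {k: [] for k in fit_result.ml_params}
    failures = 0
    for i in range(n_datasets):
        s = int(ds_seeds[i] % (2**31 - 1)) + 1
        req = cs.SimRequest(n1=n1, n2=n2, num_sites=n_snps, seed=s)
        jsfs, _, _ = cs.simulate_sfs(model, req)
        try:
            refit = fit(jsfs, builder, bounds, schedule=schedule, seed=s,
                        init=fit_result.ml_params)
        except Exception:
            failures += 1
            continue
        for k, v in refit.ml_params.items():
            estimates[k].append(v)
    fit_result.n_refit_failures = failures
    ci = {k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
          for k, v in estimates.items() if v}
    fit_result.ci95 = ci
    return ci


@dataclass(frozen=True)
class PcaFitReport:
    observed_pc: tuple[float, float]
    inside_95: bool
    mahalanobis2: float
    threshold2: float
    explained: tuple[float, float]
    degenerate: bool


def pca_fit_check(observed: JointSFS, builder,
                  ci95: dict[str, tuple[float, float]],
                  n_sims: int = 10_000, sites_per_sim: int | None = None,
                  seed: int = 1) -> PcaFitReport:
    """Project the observed spectrum into PCA space of CI-sampled simulations.

    Draws parameters uniformly from the per-parameter 95% CI ranges,
    simulates a joint SFS per draw (``sites_per_sim`` polymorphic sites,
    default = observed total), converts spectra to entry-proportion vectors,
    runs PCA on the simulated cloud and projects the observed vector.  The
    observed dataset is declared inside the cloud's 95% region when its
    squared Mahalanobis distance on (PC1, PC2) does not exceed the empirical
    95th percentile of the simulated points' own distances.
    """
    dim = (observed.n1 + 1) * (observed.n2 + 1)
    if n_sims < 3:
        raise ValidationError("n_sims too small for a PCA cloud")
    if sites_per_sim is None:
        sites_per_sim = max(int(observed.total), 1)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 555]))
    n1, n2 = observed.n1 // 2, observed.n2 // 2
    vectors = np.empty((n_sims, dim))
    for i in range(n_sims):
        params = _uniform_in_bounds(rng, ci95, {k: False for k in ci95})
        model = builder(params)
        s = int(rng.integers(1, 2**31 - 1))
        jsfs, _, _ = cs.simulate_sfs(
            model, cs.SimRequest(n1=n1, n2=n2, num_sites=sites_per_sim, seed=s))
        vectors[i] = (jsfs.matrix / jsfs.total).ravel()
    obs_vec = (np.asarray(observed.matrix) / observed.total).ravel()

    mean = vectors.mean(axis=0)
    centered = vectors - mean
    if np.allclose(centered, 0):
        return PcaFitReport((0.0, 0.0), True, 0.0, 0.0, (0.0, 0.0),
                            degenerate=True)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    pcs = vt[:2]
    var = svals**2 / (n_sims - 1)
    explained = (float(var[0] / var.sum()), float(var[1] / var.sum()))
    sim_proj = centered @ pcs.T
    obs_proj = (obs_vec - mean) @ pcs.T
    cov = np.cov(sim_proj.T)
    cov_inv = np.linalg.pinv(np.atleast_2d(cov))
    d2 = lambda p: float(p @ cov_inv @ p)
    sim_d2 = np.array([d2(p) for p in sim_proj])
    thr = float(np.percentile(sim_d2, 95))
    obs_d2 = d2(obs_proj)
    return PcaFitReport(observed_pc=(float(obs_proj[0]), float(obs_proj[1])),
                        inside_95=bool(obs_d2 <= thr), mahalanobis2=obs_d2,
                        threshold2=thr, explained=explained, degenerate=False)
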