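"""Benchmarking protocols: correlations, baselines, ablations, and inference.

Performance throughout is Pearson correlation between predicted and observed
*difference* trajectories — each trajectory baseline-normalized by its t = 0
value for time-series evaluations, or control-subtracted (stimulated control
at the evaluation timepoint) for zero-shot drug prediction.  Naive baselines,
bootstrap significance, ROC analysis of up/down calls, seed stability, and
in-silico kinase-substrate inference mirror the same conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from ._utils import rng_from_seed
from .io import PhosphoTimeCourse
from .model import ModelConfig, PhosphoModel, make_no_pkn_variant  # noqa: F401
from .rnn import DRUG_INPUT, PerturbationDesign
from .synthsim import SyntheticDataset, generate_timecourse
from .time_map import fit_anchors_from_reference_site
from .trainer import TrainingConfig, train

#: default evaluation timepoints for zero-shot drug protocols: None pools the
#: control-subtracted differences over the full sampled trajectory
DEFAULT_EVAL_TIME: float | None = None


@dataclass
class EvaluationReport:
    """Collected benchmark outputs (tidy frames; empty when not computed)."""

    correlations: pd.DataFrame = field(default_factory=pd.DataFrame)
    aucs: pd.DataFrame = field(default_factory=pd.DataFrame)
    p_values: pd.DataFrame = field(default_factory=pd.DataFrame)
    cv_summary: dict = field(default_factory=dict)


@dataclass
class KSInferenceResult:
    """Per-kinase classification of candidate substrate phosphosites."""

    validated: dict[str, list[str]]
    predicted_only: dict[str, list[str]]
    database_only: dict[str, list[str]]
    threshold: float


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def baseline_subtract_t0(tc: PhosphoTimeCourse) -> PhosphoTimeCourse:
    """Subtract each trajectory's t = 0 value (idempotent)."""
    hits = np.flatnonzero(np.isclose(tc.times, 0.0))
    if hits.size == 0:
        raise ValueError("t = 0 not present in the time course")
    k0 = int(hits[0])
    values = tc.values - tc.values[:, k0:k0 + 1, :]
    mask = tc.mask & tc.mask[:, k0:k0 + 1, :]
    return PhosphoTimeCourse(values, mask, list(tc.sample_ids),
                             tc.times.copy(), list(tc.site_ids))


def pearson_differential(pred: np.ndarray, obs: np.ndarray,
                         pred_control: np.ndarray | float = 0.0,
                         obs_control: np.ndarray | float = 0.0) -> float:
    """Pearson r of (pred - pred_control) vs (obs - obs_control)."""
    dp = np.asarray(pred, dtype=float) - pred_control
    do = np.asarray(obs, dtype=float) - obs_control
    dp, do = dp.ravel(), do.ravel()
    if dp.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(dp) == 0 or np.std(do) == 0:
        raise ValueError("undefined correlation: zero variance in differences")
    return float(stats.pearsonr(dp, do).statistic)


def naive_drug_baseline(held_out: str,
                        responses: dict[str, np.ndarray]) -> np.ndarray:
    """Predict the held-out drug as the mean response of the remaining drugs."""
    rest = [v for d, v in responses.items() if d != held_out]
    if not rest:
        raise ValueError("no remaining drugs for the naive baseline")
    return np.mean(np.stack(rest), axis=0)


def bootstrap_compare(pred_a: np.ndarray, pred_b: np.ndarray, obs: np.ndarray,
                      controls: tuple | None = None, n_boot: int = 100_000,
                      seed: int = 0) -> float:
    """One-sided bootstrap p-value that model A's correlation beats model B's.

    Phosphosites are resampled with replacement (sites are the replication
    unit); p = (1 + #{r_B > r_A} + 0.5 #{r_B = r_A}) / (n_boot + 1), so p is
    never exactly 0 and identical predictors give p near 0.5.
    """
    pa, pb, ob = (np.asarray(v, dtype=float).ravel()
                  for v in (pred_a, pred_b, obs))
    if controls is not None:
        ca, cb, co = controls
        pa, pb, ob = pa - np.ravel(ca), pb - np.ravel(cb), ob - np.ravel(co)
    n = pa.size
    if n < 3:
        raise ValueError("need at least 3 sites for bootstrap comparison")
    rng = rng_from_seed(seed)
    exceed = 0.0
    chunk = 5000
    for start in range(0, n_boot, chunk):
        m = min(chunk, n_boot - start)
        idx = rng.integers(0, n, size=(m, n))
        ra = _rowwise_pearson(pa[idx], ob[idx])
        rb = _rowwise_pearson(pb[idx], ob[idx])
        exceed += float(np.sum(rb > ra) + 0.5 * np.sum(rb == ra))
    return (1 + exceed) / (n_boot + 1)


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    num = np.sum(A * B, axis=1)
    den = np.sqrt(np.sum(A**2, axis=1) * np.sum(B**2, axis=1))
    out = np.full(A.shape[0], -np.inf)  # degenerate resamples never "win"
    good = den > 0
    out[good] = num[good] / den[good]
    return out


def updown_roc(pred: np.ndarray, obs: np.ndarray,
               fc_threshold: float = 1.0) -> dict[str, float | None]:
    """AUC for calling clearly up-/down-regulated sites from centered scores.

    Observed |difference| >= threshold labels a site as up or down; the
    predicted differences serve as continuous scores.  A direction lacking
    positives or negatives is reported as missing (None).
    """
    pred, obs = np.ravel(pred), np.ravel(obs)
    out: dict[str, float | None] = {}
    for direction, labels, scores in (("up", obs >= fc_threshold, pred),
                                      ("down", obs <= -fc_threshold, -pred)):
        if labels.any() and (~labels).any():
            out[direction] = float(roc_auc_score(labels, scores))
        else:
            out[direction] = None
    return out


def seed_stability(fit_fn, n_seeds: int = 10, zero_tol: float = 1e-8):
    """Coefficient of variation of predictions across random initializations.

    ``fit_fn(seed)`` must return a prediction array of a fixed shape.  The CV
    (sd/mean) is computed per entry; entries whose mean magnitude is below
    ``zero_tol`` are reported as NaN (CV undefined near zero).
    """
    if n_seeds < 2:
        raise ValueError("need at least 2 seeds")
    preds = np.stack([np.asarray(fit_fn(seed), dtype=float)
                      for seed in range(n_seeds)])
    mean = preds.mean(axis=0)
    sd = preds.std(axis=0, ddof=1)
    cv = np.where(np.abs(mean) > zero_tol, sd / np.where(
        np.abs(mean) > zero_tol, np.abs(mean), 1.0), np.nan)
    finite = cv[np.isfinite(cv)]
    summary = {
        "n_entries": int(cv.size),
        "n_defined": int(finite.size),
        "median_cv": float(np.median(finite)) if finite.size else np.nan,
        "frac_below_13pct": (float(np.mean(finite < 0.13))
                             if finite.size else np.nan),
    }
    return cv, summary


# ---------------------------------------------------------------------------
# model fitting helper
# ---------------------------------------------------------------------------

def fit_model(ds: SyntheticDataset, train_samples: list[str] | None = None,
              cfg: TrainingConfig | None = None,
              model_cfg: ModelConfig | None = None,
              times: np.ndarray | None = None,
              fixed_anchors: np.ndarray | None = None) -> PhosphoModel:
    """Construct and train a model on (a subset of) a synthetic dataset."""
    cfg = cfg or TrainingConfig(epochs=300, batch_mode="full")
    model_cfg = model_cfg or ModelConfig(seed=cfg.random_seed)
    tc = ds.timecourse
    if times is not None:
        tc = tc.subset_times(times)
    model = PhosphoModel(ds.ground_truth.network, ds.site_assignment,
                         ds.design, tc.times, model_cfg,
                         fixed_anchors=fixed_anchors)
    samples = train_samples or list(ds.design.sample_ids)
    train(model, tc.subset_samples(samples), ds.design.subset(samples), cfg)
    return model


# ---------------------------------------------------------------------------
# interpolation protocols
# ---------------------------------------------------------------------------

def run_downsampling_protocol(ds: SyntheticDataset,
                              fractions: list[float],
                              window: int = 30,
                              cfg: TrainingConfig | None = None,
                              seed: int = 0,
                              model_dtype: str = "float64") -> pd.DataFrame:
    """Interpolation performance vs the fraction of anchors in the window.

    Observations are the ground truth at uniformly spaced steps within the
    first ``window`` recurrent steps (plus replicate noise); the model trains
    with its time map fixed at those anchors and is scored by pooled Pearson r
    on the withheld steps, after subtracting each trajectory's first step.
    """
    cfg = cfg or TrainingConfig(epochs=300, batch_mode="full")
    rng = rng_from_seed(seed)
    steps_window = np.arange(window)
    Y = ds.noiseless_site_values(steps_window)
    noise_sd = float(ds.metadata.get("noise_sd", 0.0))
    Y_obs = Y + rng.normal(0.0, noise_sd, size=Y.shape) if noise_sd > 0 else Y
    rows = []
    for frac in fractions:
        n_anchor = int(round(frac * window))
        if n_anchor < 2:
            raise ValueError(f"fraction {frac} yields fewer than 2 anchors")
        anchor_steps = np.unique(np.round(
            np.linspace(0, window - 1, n_anchor)).astype(int))
        withheld = np.setdiff1d(steps_window, anchor_steps)
        tc = PhosphoTimeCourse(
            Y_obs[:, np.searchsorted(steps_window, anchor_steps), :],
            np.ones((Y.shape[0], anchor_steps.size, Y.shape[2]), dtype=bool),
            list(ds.design.sample_ids), anchor_steps.astype(float),
            list(ds.site_assignment.site_ids))
        model_cfg = ModelConfig(time_map_mode="fixed", seed=cfg.random_seed,
                                dtype=model_dtype)
        model = PhosphoModel(ds.ground_truth.network, ds.site_assignment,
                             ds.design, tc.times, model_cfg,
                             fixed_anchors=anchor_steps.astype(float))
        train(model, tc, ds.design, cfg)
        pred_w = model.predict_at_steps(ds.design, withheld)
        pred_0 = model.predict_at_steps(ds.design, np.array([0]))
        truth_w = Y[:, np.searchsorted(steps_window, withheld), :]
        truth_0 = Y[:, :1, :]
        r = pearson_differential(pred_w - pred_0, truth_w - truth_0)
        rows.append({"fraction": frac, "n_anchors": int(anchor_steps.size),
                     "n_withheld": int(withheld.size), "r": r})
    return pd.DataFrame(rows)


def run_interpolation_protocol(ds: SyntheticDataset,
                               held_out_times: list[float],
                               strategy: str = "reference_site",
                               reference_site: str | None = None,
                               cfg: TrainingConfig | None = None) -> pd.DataFrame:
    """Hold out timepoints during training and infer them post hoc.

    Strategies: ``linear`` (interpolate observed values between flanking
    trained times — no model), ``reference_site`` (estimate held-out anchors
    from a densely sampled single phosphosite), or ``one_to_one`` (the k-th
    time maps to recurrent step k).
    """
    if strategy not in ("linear", "reference_site", "one_to_one"):
        raise ValueError(f"unknown strategy {strategy!r}")
    all_times = ds.timecourse.times
    held = np.asarray(held_out_times, dtype=float)
    if np.any(np.isclose(held, 0.0)):
        raise ValueError("t = 0 is the baseline anchor and cannot be held out")
    train_times = np.array([t for t in all_times
                            if not np.any(np.isclose(held, t))])
    tc_all = ds.timecourse
    obs_sub = baseline_subtract_t0(tc_all)
    rows = []
    if strategy == "linear":
        for t in held:
            obs_t = tc_all.subset_times([t]).values[:, 0, :]
            lo = train_times[train_times < t].max()
            hi = train_times[train_times > t].min()
            w = (t - lo) / (hi - lo)
            v_lo = tc_all.subset_times([lo]).values[:, 0, :]
            v_hi = tc_all.subset_times([hi]).values[:, 0, :]
            pred_t = (1 - w) * v_lo + w * v_hi
            v0 = tc_all.subset_times([0.0]).values[:, 0, :]
            r = pearson_differential(pred_t - v0, obs_t - v0)
            rows.append({"time": float(t), "strategy": strategy, "r": r})
        return pd.DataFrame(rows)

    model = fit_model(ds, cfg=cfg, times=train_times)
    learned = model.anchors()[0]
    if strategy == "one_to_one":
        full_anchor = {float(t): float(np.flatnonzero(
            np.isclose(all_times, t))[0]) for t in held}
    else:
        ref_site = reference_site or _most_dynamic_site(obs_sub)
        control = ds.design.sample_ids[0]
        ctrl_design = ds.design.subset([control])
        traj = model.site_step_trajectory(ctrl_design, ref_site)[0]
        ref_idx = tc_all.site_ids.index(ref_site)
        ctrl_row = tc_all.sample_index(control)
        known = {int(np.flatnonzero(np.isclose(all_times, t))[0]): float(a)
                 for t, a in zip(train_times, learned)}
        fitted = fit_anchors_from_reference_site(
            tc_all.values[ctrl_row, :, ref_idx], traj,
            model.config.n_steps, known_anchors=known)
        full_anchor = {float(all_times[k]): float(fitted[k])
                       for k in range(all_times.size)}
    pred0 = model.predict_at_steps(ds.design, np.array([0]))[:, 0, :]
    for t in held:
        m = np.array([full_anchor[float(t)]])
        lo = int(np.floor(m[0]))
        hi = min(lo + 1, model.config.n_steps - 1)
        dm = float(m[0] - lo)
        y = model.predict_at_steps(ds.design, np.array([lo, hi]))
        pred_t = (1 - dm) * y[:, 0, :] + dm * y[:, 1, :]
        obs_t = obs_sub.subset_times([t]).values[:, 0, :]
        r = pearson_differential(pred_t - pred0, obs_t)
        rows.append({"time": float(t), "strategy": strategy, "r": r,
                     "anchor": float(m[0])})
    return pd.DataFrame(rows)


def _most_dynamic_site(tc_sub: PhosphoTimeCourse) -> str:
    var = tc_sub.values.var(axis=(0, 1))
    return tc_sub.site_ids[int(np.argmax(var))]


# ---------------------------------------------------------------------------
# zero-shot drug protocols
# ---------------------------------------------------------------------------

def zero_shot_loo(ds: SyntheticDataset, held_out_drug: str,
                  cfg: TrainingConfig | None = None,
                  eval_time: float | None = DEFAULT_EVAL_TIME,
                  model_cfg: ModelConfig | None = None) -> dict:
    """Train without one drug's sample and predict its response zero-shot.

    Returns model and naive-baseline correlations on control-subtracted
    differences, pooled over the full trajectory (or restricted to a single
    timepoint when ``eval_time`` is given).
    """
    design = ds.design
    if held_out_drug not in design.drugs:
        raise KeyError(f"unknown drug {held_out_drug!r}")
    col = design.drugs.index(held_out_drug)
    held_samples = [design.sample_ids[i]
                    for i in np.flatnonzero(design.drug_matrix[:, col])]
    train_samples = [s for s in design.sample_ids if s not in held_samples]
    model = fit_model(ds, train_samples=train_samples, cfg=cfg,
                      model_cfg=model_cfg)
    preds = model.predict(design)
    obs = ds.timecourse.values
    if eval_time is None:
        kt = slice(None)
    else:
        kt = int(np.flatnonzero(np.isclose(ds.timecourse.times, eval_time))[0])
    control = design.sample_ids[0]
    i_ctrl = ds.timecourse.sample_index(control)
    i_held = ds.timecourse.sample_index(held_samples[0])
    obs_diff = {d: obs[ds.timecourse.sample_index(
        design.sample_ids[1 + j]), kt] - obs[i_ctrl, kt]
        for j, d in enumerate(design.drugs)}
    r_model = pearson_differential(preds[i_held, kt], obs[i_held, kt],
                                   preds[i_ctrl, kt], obs[i_ctrl, kt])
    naive = naive_drug_baseline(held_out_drug, obs_diff)
    r_naive = pearson_differential(naive, obs_diff[held_out_drug])
    return {"drug": held_out_drug, "r_model": r_model, "r_naive": r_naive,
            "model": model}


def run_drug_scaling_protocol(gt, n_drugs_grid: list[int],
                              n_folds: int = 3, n_seeds: int = 3,
                              cfg: TrainingConfig | None = None,
                              eval_time: float | None = DEFAULT_EVAL_TIME,
                              base_seed: int = 0,
                              noise_sd: float | None = None,
                              model_dtype: str = "float64") -> pd.DataFrame:
    """Zero-shot performance as a function of training-set drug count.

    For each training size n, each replicate seed samples n + 1 drugs that
    each inhibit a distinct node; leave-one-drug-out folds train on n drugs
    and predict the held-out one.
    """
    targetable = [nd for nd in gt.network.node_ids]
    rows = []
    for n in n_drugs_grid:
        if n + 1 > len(targetable):
            raise ValueError(f"not enough targetable nodes for {n} drugs")
        for s in range(n_seeds):
            seed = base_seed + 1000 * s
            rng = rng_from_seed(seed)
            targets = [str(t) for t in
                       rng.choice(targetable, size=n + 1, replace=False)]
            ds = generate_timecourse(gt, targets, seed=seed,
                                     noise_sd=noise_sd)
            fold_drugs = [ds.design.drugs[int(i)] for i in
                          rng.choice(len(ds.design.drugs),
                                     size=min(n_folds, n + 1), replace=False)]
            if cfg is None:
                run_cfg = TrainingConfig(epochs=300, batch_mode="full",
                                         random_seed=seed)
            else:
                run_cfg = replace(cfg, random_seed=seed)
            mc = ModelConfig(seed=seed, dtype=model_dtype)
            for drug in fold_drugs:
                res = zero_shot_loo(ds, drug, cfg=run_cfg, eval_time=eval_time,
                                    model_cfg=mc)
                rows.append({"n_drugs": n, "seed": seed, "drug": drug,
                             "r_model": res["r_model"],
                             "r_naive": res["r_naive"]})
    return pd.DataFrame(rows)


def run_shuffled_label_control(ds: SyntheticDataset, held_out_drug: str,
                               cfg: TrainingConfig | None = None,
                               eval_time: float | None = DEFAULT_EVAL_TIME,
                               seed: int = 0) -> dict:
    """Zero-shot evaluation after permuting sample labels (negative control)."""
    from .synthsim import shuffle_labels
    return zero_shot_loo(shuffle_labels(ds, seed), held_out_drug,
                         cfg=cfg, eval_time=eval_time)


# ---------------------------------------------------------------------------
# ablation ladder
# ---------------------------------------------------------------------------

ABLATION_LADDER = ("baseline", "time_map", "scalar", "embedding")


def run_ablation_protocol(ds: SyntheticDataset, n_folds: int = 5,
                          cfg: TrainingConfig | None = None,
                          variants: tuple[str, ...] = ABLATION_LADDER,
                          eval_time: float | None = DEFAULT_EVAL_TIME,
                          seed: int = 0) -> pd.DataFrame:
    """Cross-validated comparison of the model-configuration ladder.

    ``baseline``: equally spaced fixed anchors + identity site map;
    ``time_map``: trainable time map + identity site map; ``scalar``:
    trainable time map + per-site affine map; ``embedding``: the full model.
    Folds hold out samples; performance is the control-subtracted r of the
    held-out samples at the evaluation timepoint.
    """
    rng = rng_from_seed(seed)
    drug_samples = list(ds.design.sample_ids[1:])
    folds = np.array_split(rng.permutation(drug_samples),
                           min(n_folds, len(drug_samples)))
    L = 150
    K = ds.timecourse.times.size
    rows = []
    for variant in variants:
        if variant == "baseline":
            mc = ModelConfig(site_map_mode="identity", time_map_mode="fixed",
                             seed=seed)
            anchors = np.round(np.linspace(0, L - 1, K))
        else:
            site_mode = {"time_map": "identity", "scalar": "scalar",
                         "embedding": "embedding"}[variant]
            mc = ModelConfig(site_map_mode=site_mode, seed=seed)
            anchors = None
        rs = []
        for fold in folds:
            train_samples = [s for s in ds.design.sample_ids
                             if s not in set(fold)]
            run_cfg = cfg or TrainingConfig(epochs=300, batch_mode="full",
                                            random_seed=seed)
            model = fit_model(ds, train_samples=train_samples, cfg=run_cfg,
                              model_cfg=mc, fixed_anchors=anchors)
            preds = model.predict(ds.design)
            kt = (slice(None) if eval_time is None else
                  int(np.flatnonzero(
                      np.isclose(ds.timecourse.times, eval_time))[0]))
            i_ctrl = ds.timecourse.sample_index(ds.design.sample_ids[0])
            for s in fold:
                i = ds.timecourse.sample_index(str(s))
                rs.append(pearson_differential(
                    preds[i, kt], ds.timecourse.values[i, kt],
                    preds[i_ctrl, kt], ds.timecourse.values[i_ctrl, kt]))
        rows.append({"variant": variant, "r_mean": float(np.mean(rs)),
                     "r_sd": float(np.std(rs)), "n_folds": len(folds)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# kinase-substrate inference
# ---------------------------------------------------------------------------

def infer_kinase_substrates(model: PhosphoModel, kinases: list[str],
                            reference: list[tuple[str, str]],
                            data_sites: list[str] | None = None,
                            threshold: float = 0.5,
                            control_design: PerturbationDesign | None = None
                            ) -> KSInferenceResult:
    """In-silico kinase inhibition restricted to direct network neighbors.

    Each kinase receives the fixed -5 inhibitory input on top of the control
    stimulation; phosphosites whose control-subtracted prediction at the last
    timepoint drops by at least ``threshold`` *and* whose node is one directed
    edge downstream of the kinase are called predicted substrates, then
    classified against the reference pairs (restricted to measured sites).
    """
    net = model.network
    sites = data_sites if data_sites is not None else model.sites.site_ids
    measured = [s for s in model.sites.site_ids if s in set(sites)]
    if control_design is None:
        # first design sample is the stimulation-only control by convention
        control_design = model.design_space.subset(
            [model.design_space.sample_ids[0]])
    x_ctrl = model.build_inputs(control_design)
    pred_ctrl = model.forward(x_ctrl)[:, -1, :][0]
    validated: dict[str, list[str]] = {}
    predicted_only: dict[str, list[str]] = {}
    database_only: dict[str, list[str]] = {}
    g = net.to_digraph()
    site_idx = {s: j for j, s in enumerate(model.sites.site_ids)}
    for kinase in kinases:
        if kinase not in net.node_ids:
            raise KeyError(f"kinase {kinase!r} absent from the network")
        x = x_ctrl.copy()
        x[0, net.node_index(kinase)] += DRUG_INPUT
        pred = model.forward(x)[:, -1, :][0]
        delta = pred - pred_ctrl
        direct = set(g.successors(kinase))
        predicted = [s for s in measured
                     if model.sites.site_to_node[s] in direct
                     and delta[site_idx[s]] <= -threshold]
        ref_sites = [s for k, s in reference if k == kinase and s in set(measured)]
        pset, rset = set(predicted), set(ref_sites)
        validated[kinase] = sorted(pset & rset)
        predicted_only[kinase] = sorted(pset - rset)
        database_only[kinase] = sorted(rset - pset)
    return KSInferenceResult(validated, predicted_only, database_only, threshold)


def naive_de_inference(obs_inhibitor: np.ndarray, obs_stimulated: np.ndarray,
                       site_ids: list[str], kinase: str,
                       reference: list[tuple[str, str]],
                       threshold: float = 0.5) -> KSInferenceResult:
    """Reference overlap of plainly differential phosphosites (no model).

    Sites whose |inhibitor - stimulated| difference passes the threshold are
    intersected with the reference pairs of the inhibitor's target kinase.
    """
    obs_i = np.ravel(obs_inhibitor)
    obs_s = np.ravel(obs_stimulated)
    if obs_i.size != len(site_ids) or obs_s.size != len(site_ids):
        raise ValueError("observations must align with site_ids")
    if len(site_ids) == 0:
        raise ValueError("no shared sites between the two conditions")
    perturbed = {s for s, d in zip(site_ids, obs_i - obs_s)
                 if abs(d) >= threshold}
    ref_sites = {s for k, s in reference if k == kinase and s in set(site_ids)}
    return KSInferenceResult(
        validated={kinase: sorted(perturbed & ref_sites)},
        predicted_only={kinase: sorted(perturbed - ref_sites)},
        database_only={kinase: sorted(ref_sites - perturbed)},
        threshold=threshold)
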