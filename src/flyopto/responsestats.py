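"""Event-triggered response statistics.

Traces from all accepted activation events are aligned to stimulus onset on
a common relative-time grid, mirrored so that the activated side is always
"right" (positive yaw/lateral = toward the stimulus), and summarized by
their mean over a post-onset window (100 ms by default).  Inference is
nonparametric, with the activation event as the resampling unit:

* bias-corrected and accelerated (BCa) percentile bootstrap confidence
  intervals at 95% (trace error bands) and 99% (window averages);
* a paired permutation test of post-vs-pre differences (random exchange of
  pre/post labels within events) for deviation from baseline, reported
  significant at p < 0.01.

Somatic maps bin the body-frame hit locations and show the per-bin mean
windowed response, masking bins with too few events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtr, ndtri

from flyopto import hitdetect
from flyopto.kinematics import (
    KinematicSeries,
    ResponseWindowConfig,
    contralateral_change_trace,
    fold_change_trace,
)

__all__ = [
    "ResponseEnsemble",
    "IntervalEstimate",
    "align_events",
    "window_average",
    "bca_ci",
    "permutation_test",
    "somatic_map",
    "SomaticMap",
    "group_summary",
]


@dataclass
class ResponseEnsemble:
    """Event-aligned traces on a shared relative-time axis.

    Trace arrays are (n_events, n_times); `events` carries one metadata row
    per trace (target_class, side, phase, body-frame hit coordinates).
    Yaw and lateral traces are already symmetrized (+ = toward the
    activated side).
    """

    t_rel: np.ndarray
    fold_vpar: np.ndarray
    v_rot: np.ndarray
    v_perp: np.ndarray
    events: pd.DataFrame
    limb_dist: dict = field(default_factory=dict)  # pair -> (n_events, n_times)
    dropped: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.events)

    def signal(self, name: str) -> np.ndarray:
        if name in ("fold_vpar", "v_rot", "v_perp"):
            return getattr(self, name)
        if name.startswith("dist_"):
            return self.limb_dist[name.removeprefix("dist_")]
        raise KeyError(name)

    def subset(self, mask) -> "ResponseEnsemble":
        mask = np.asarray(mask)
        return ResponseEnsemble(
            t_rel=self.t_rel,
            fold_vpar=self.fold_vpar[mask],
            v_rot=self.v_rot[mask],
            v_perp=self.v_perp[mask],
            events=self.events.loc[mask].reset_index(drop=True),
            limb_dist={k: v[mask] for k, v in self.limb_dist.items()},
        )


def align_events(per_fly: dict, events,
                 config: ResponseWindowConfig = ResponseWindowConfig(),
                 limb_dist_pairs: tuple = ()) -> ResponseEnsemble:
    """Build a ResponseEnsemble from detected events.

    Parameters
    ----------
    per_fly : dict
        fly_id -> (PoseTrack, KinematicSeries) computed on the analyzed
        (post-stimulus) track.
    events : iterable of hitdetect.ActivationEvent
        Already-excluded events are skipped; events failing the edge or
        pre-stimulus-speed filters are dropped here and recorded in
        ``ensemble.dropped``.
    limb_dist_pairs : tuple of {"fore","mid","hind"}
        Contralateral distance-change traces to attach.
    """
    rows, drops = [], []
    fold_traces, rot_traces, perp_traces = [], [], []
    dist_traces = {p: [] for p in limb_dist_pairs}
    t_rel = None
    for ev in events:
        if ev.excluded:
            continue
        track, series = per_fly[ev.fly_id]
        fc = fold_change_trace(series, ev.onset_frame, config)
        if fc.excluded:
            drops.append({"fly_id": ev.fly_id, "onset_frame": ev.onset_frame,
                          "reason": fc.reason})
            continue
        pre = int(round(config.pre_window_s * series.fps))
        post = int(round(config.horizon_s * series.fps))
        sl = slice(ev.onset_frame - pre, ev.onset_frame + post + 1)
        side, tr = hitdetect.symmetrize(
            ev.side, {"v_rot": series.v_rot[sl], "v_perp": series.v_perp[sl]}
        )
        t_rel = fc.t_rel
        fold_traces.append(fc.trace)
        rot_traces.append(tr["v_rot"])
        perp_traces.append(tr["v_perp"])
        for p in limb_dist_pairs:
            dist_traces[p].append(contralateral_change_trace(
                track, p, ev.onset_frame, config)[1])
        bx, by = ev.patch_center_body_xy or (np.nan, np.nan)
        rows.append({"fly_id": ev.fly_id, "onset_frame": ev.onset_frame,
                     "target_class": ev.target_class, "side": ev.side,
                     "limb_phase": ev.limb_phase, "body_x_mm": bx,
                     "body_y_mm": by, "pre_mean_mm_s": fc.pre_mean})

    nt = len(t_rel) if t_rel is not None else 0
    def _stack(lst):
        return np.array(lst) if lst else np.empty((0, nt))
    return ResponseEnsemble(
        t_rel=t_rel if t_rel is not None else np.empty(0),
        fold_vpar=_stack(fold_traces),
        v_rot=_stack(rot_traces),
        v_perp=_stack(perp_traces),
        events=pd.DataFrame(rows),
        limb_dist={p: _stack(v) for p, v in dist_traces.items()},
        dropped=pd.DataFrame(drops),
    )


def window_average(ensemble: ResponseEnsemble, signal: str = "fold_vpar",
                   window: tuple = (0.0, 0.1)) -> tuple[np.ndarray, float]:
    """Per-event time-means over `window` (inclusive) and their group mean."""
    lo, hi = window
    if lo < ensemble.t_rel[0] - 1e-9 or hi > ensemble.t_rel[-1] + 1e-9:
        raise ValueError(f"window {window} outside trace time axis")
    mask = (ensemble.t_rel >= lo - 1e-9) & (ensemble.t_rel <= hi + 1e-9)
    per_event = ensemble.signal(signal)[:, mask].mean(axis=1)
    return per_event, float(per_event.mean()) if len(per_event) else np.nan


# ------------------------------------------------------------ inference

@dataclass
class IntervalEstimate:
    """Point estimate with a bootstrap confidence interval."""

    estimate: float
    ci_lo: float
    ci_hi: float
    level: float
    n_boot: int
    p_value: float | None = None
    seed: int | None = None
    method: str = "bca"


def _boot_statistics(values: np.ndarray, statistic, n_boot: int,
                     rng: np.random.Generator) -> np.ndarray:
    n = len(values)
    idx = rng.integers(0, n, size=(n_boot, n))
    resamples = values[idx]
    try:
        out = np.asarray(statistic(resamples, axis=1), dtype=float)
        if out.shape != (n_boot,):
            raise TypeError
        return out
    except TypeError:
        return np.array([statistic(row) for row in resamples], dtype=float)


def bca_ci(values, statistic=np.mean, level: float = 0.95,
           n_boot: int = 10_000, seed=None) -> IntervalEstimate:
    """Bias-corrected and accelerated percentile bootstrap interval.

    The bias correction z0 comes from the fraction of bootstrap replicates
    below the point estimate; the acceleration a from the jackknife skewness
    of the statistic.  Degenerate cases (constant data, or a bootstrap
    distribution entirely on one side of the estimate) fall back to the
    plain percentile interval with a warning.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two values to bootstrap")
    rng = np.random.default_rng(seed)
    theta = float(statistic(values))
    if np.ptp(values) == 0.0:
        return IntervalEstimate(theta, theta, theta, level, n_boot, seed=seed,
                                method="degenerate")
    boots = _boot_statistics(values, statistic, n_boot, rng)
    alpha = (1.0 - level) / 2.0

    prop = np.mean(boots < theta)
    if prop in (0.0, 1.0) or np.ptp(boots) == 0.0:
        warnings.warn("degenerate bootstrap distribution; falling back to "
                      "percentile interval", RuntimeWarning, stacklevel=2)
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
        return IntervalEstimate(theta, float(lo), float(hi), level, n_boot,
                                seed=seed, method="percentile")
    z0 = ndtri(prop)

    # jackknife acceleration
    n = len(values)
    jack = np.empty(n)
    mask = ~np.eye(n, dtype=bool)
    for i in range(n):
        jack[i] = statistic(values[mask[i]])
    d = jack.mean() - jack
    denom = (d @ d) ** 1.5
    a = float((d**3).sum() / (6.0 * denom)) if denom > 0 else 0.0

    z_lo, z_hi = ndtri(alpha), ndtri(1.0 - alpha)
    def _adj(z):
        zz = z0 + z
        return ndtr(z0 + zz / (1.0 - a * zz))
    lo, hi = np.quantile(boots, [_adj(z_lo), _adj(z_hi)])
    return IntervalEstimate(theta, float(lo), float(hi), level, n_boot,
                            seed=seed, method="bca")


def permutation_test(pre_values, post_values, n_perm: int = 10_000,
                     seed=None) -> float:
    """Paired permutation test of mean(post - pre) against zero.

    The null is built by randomly exchanging the pre/post labels within
    each event (equivalently, flipping the sign of each paired difference);
    two-sided p = (1 + #{|T*| >= |T|}) / (n_perm + 1).
    """
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (same shape)")
    n = len(pre)
    if n < 2:
        raise ValueError("need at least two events for a permutation test")
    rng = np.random.default_rng(seed)
    d = post - pre
    t_obs = abs(d.mean())
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    t_null = np.abs((signs * d).mean(axis=1))
    return float((1 + np.sum(t_null >= t_obs - 1e-12)) / (n_perm + 1))


# ----------------------------------------------------------- somatic map

@dataclass
class SomaticMap:
    """Binned body-frame response map (+x toward the head, +y left)."""

    mean: np.ma.MaskedArray  # (ny, nx), masked where counts < min_count
    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray


def somatic_map(body_xy, scalars, bin_mm: float = 0.1, min_count: int = 5,
                extent: tuple | None = None) -> SomaticMap:
    """Per-bin mean of a windowed response scalar over body-frame hit sites.

    `extent` is (x_min, x_max, y_min, y_max) in mm; by default it snaps to
    the data range on a `bin_mm` grid.  Bin counts over the extent sum to
    the number of events inside it.
    """
    body_xy = np.asarray(body_xy, dtype=float).reshape(-1, 2)
    scalars = np.asarray(scalars, dtype=float)
    if len(body_xy) == 0:
        empty = np.ma.masked_all((0, 0))
        return SomaticMap(empty, np.zeros((0, 0)), np.zeros(1), np.zeros(1))
    if extent is None:
        x_min = np.floor(body_xy[:, 0].min() / bin_mm) * bin_mm
        x_max = np.ceil(body_xy[:, 0].max() / bin_mm + 1e-9) * bin_mm
        y_min = np.floor(body_xy[:, 1].min() / bin_mm) * bin_mm
        y_max = np.ceil(body_xy[:, 1].max() / bin_mm + 1e-9) * bin_mm
    else:
        x_min, x_max, y_min, y_max = extent
    x_edges = np.arange(x_min, x_max + bin_mm / 2, bin_mm)
    y_edges = np.arange(y_min, y_max + bin_mm / 2, bin_mm)
    mean, _, _, _ = sps.binned_statistic_2d(
        body_xy[:, 0], body_xy[:, 1], scalars, statistic="mean",
        bins=[x_edges, y_edges])
    counts, _, _, _ = sps.binned_statistic_2d(
        body_xy[:, 0], body_xy[:, 1], None, statistic="count",
        bins=[x_edges, y_edges])
    mean = np.ma.masked_invalid(mean.T)  # -> (ny, nx)
    counts = counts.T
    mean = np.ma.masked_where(counts < min_count, mean)
    return SomaticMap(mean, counts, x_edges, y_edges)


# -------------------------------------------------------------- summary

def group_summary(ensemble: ResponseEnsemble, signal: str = "fold_vpar",
                  group_by: str = "target_class", window: tuple = (0.0, 0.1),
                  baseline: float | None = None,
                  ci_level: float = 0.99, n_boot: int = 10_000,
                  n_perm: int = 10_000, seed=None) -> pd.DataFrame:
    """Tidy per-group summary: windowed mean, BCa CI, and permutation p.

    Fold-change is already normalized per event, so its estimate is the
    post-window mean (baseline 1).  Signed signals (yaw, lateral, limb
    distances) are reported as the *change from baseline*: the per-event
    post-window mean minus pre-window mean (baseline 0).  Conditioning on a
    hit selects for poses that expose the struck side, which biases raw
    signed velocities identically before and after onset; differencing
    cancels that sampling bias, and the paired permutation test is immune
    to it by construction.
    """
    differenced = signal != "fold_vpar"
    if baseline is None:
        baseline = 0.0 if differenced else 1.0
    pre_window = (float(ensemble.t_rel[0]), 0.0)
    rows = []
    ss = np.random.SeedSequence(seed)
    for group, child in zip(
        sorted(ensemble.events[group_by].unique()),
        ss.spawn(len(ensemble.events[group_by].unique())),
    ):
        sub = ensemble.subset((ensemble.events[group_by] == group).to_numpy())
        post_vals, _ = window_average(sub, signal, window)
        pre_vals, _ = window_average(sub, signal, pre_window)
        ci_vals = post_vals - pre_vals if differenced else post_vals
        est = float(ci_vals.mean()) if len(ci_vals) else np.nan
        child_seed = int(child.generate_state(1)[0] % (2**31))
        if len(post_vals) >= 2:
            ci = bca_ci(ci_vals, np.mean, ci_level, n_boot, seed=child_seed)
            p = permutation_test(pre_vals, post_vals, n_perm, seed=child_seed)
        else:
            ci = IntervalEstimate(est, np.nan, np.nan, ci_level, 0)
            p = np.nan
        rows.append({"group": group, "signal": signal, "n": len(ci_vals),
                     "estimate": est, "ci_lo": ci.ci_lo, "ci_hi": ci.ci_hi,
                     "ci_level": ci_level, "p": p, "baseline": baseline,
                     "significant": bool(p < 0.01) if p == p else False,
                     "seed": child_seed})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- plotting

def plot_traces(ensemble: ResponseEnsemble, signal: str = "fold_vpar",
                group_by: str = "target_class", ax=None, ci_level: float = 0.95,
                n_boot: int = 1000, seed=0):
    """Group-mean traces with bootstrap error bands (matplotlib axis)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for group in sorted(ensemble.events[group_by].unique()):
        sub = ensemble.subset((ensemble.events[group_by] == group).to_numpy())
        traces = sub.signal(signal)
        mean = traces.mean(axis=0)
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(traces), size=(n_boot, len(traces)))
        boots = traces[idx].mean(axis=1)
        lo, hi = np.quantile(boots, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2],
                             axis=0)
        ax.plot(ensemble.t_rel, mean, label=f"{group} (n={len(sub)})")
        ax.fill_between(ensemble.t_rel, lo, hi, alpha=0.25)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time from activation onset (s)")
    ax.set_ylabel(signal)
    ax.legend(fontsize="small")
    return ax


def plot_somatic_map(smap: SomaticMap, ax=None, cmap="coolwarm", **imshow_kw):
    """Somatic map image in body-frame mm, head to the right."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(
        smap.mean, origin="lower", cmap=cmap,
        extent=(smap.x_edges[0], smap.x_edges[-1],
                smap.y_edges[0], smap.y_edges[-1]),
        aspect="equal", **imshow_kw)
    ax.set_xlabel("body axis (mm, + head)")
    ax.set_ylabel("lateral (mm, + left)")
    return im
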