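"""Genotype calling from two-channel intensities with inbred correction,
off-target-variant (OTV) detection, cluster quality metrics, and six-way
variant classification.

Raw channel signals are transformed to contrast x = log2(A/B) and size
y = (log2 A + log2 B)/2.  Genotypes are called per variant by a 2-D
diagonal-covariance Gaussian-mixture EM.  Two starts are tried — the
generic a-priori centers (AA at +delta, AB at 0, BB at -delta in contrast)
and a data-quantile start that rescues variants whose clusters sit far from
the generic positions — and the fit with the higher likelihood wins.
Coincident components are merged, and the surviving clusters are assigned
genotype labels a posteriori by their contrast order relative to the
a-priori positions.

Each sample's heterozygote prior weight is multiplied by 2^(-penalty/2),
where the inbred penalty runs from 0 (fully heterozygous material, e.g. F1
hybrids) to 16 (completely homozygous); this inbred correction suppresses
spurious heterozygote calls in inbred panels.  Variants whose heterozygote
cluster sits far below the homozygote intensity line (HetSO below the OTV
cut) are re-called with a fourth low-size OO cluster.

Cluster metrics follow the conventional geometric definitions: FLD is the
contrast separation between the heterozygote cluster and its nearest
homozygote in pooled within-cluster standard deviations (homFLD the
analogue between the two homozygotes); HetSO is the vertical (size) offset
of the AB center from the line through the AA and BB centers; HomRO is the
smallest signed distance of a homozygote center from zero contrast in its
expected direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

from .containers import AA, AB, BB, MISSING, OO
from .errors import ValidationError

__all__ = [
    "transform",
    "ClusterParams",
    "ClassifyThresholds",
    "ClusterModel",
    "ClusterMetrics",
    "VariantResult",
    "call_genotypes",
    "detect_otv",
    "fld",
    "hom_fld",
    "het_so",
    "hom_ro",
    "cluster_metrics",
    "classify",
    "call_variant",
    "genotype_panel",
    "PanelCallResult",
    "compare_correction",
    "Transition",
    "class_weight",
]

CATEGORIES = (
    "PolyHighResolution",
    "NoMinorHom",
    "MonoHighResolution",
    "OTV",
    "CallRateBelowThreshold",
    "Other",
)

_LABEL_CODE = {"AA": AA, "AB": AB, "BB": BB, "OO": OO}


def transform(signal_a, signal_b, floor: float = 1.0):
    """Two-channel transform: contrast x = log2(A/B), size y = mean log2
    signal; raw signals are floored before the logs."""
    a = np.maximum(np.asarray(signal_a, float), floor)
    b = np.maximum(np.asarray(signal_b, float), floor)
    la, lb = np.log2(a), np.log2(b)
    return la - lb, (la + lb) / 2.0


@dataclass
class ClusterParams:
    """EM caller settings.

    ``contrast_delta``/``het_size_offset`` place the generic a-priori
    centers; ``confidence_min`` is the posterior needed to emit a call;
    ``merge_radius`` collapses coincident fitted components;
    ``hetso_otv_cut`` routes variants to OTV re-calling.
    """

    contrast_delta: float = 1.5
    het_size_offset: float = 0.3
    confidence_min: float = 0.95
    max_iter: int = 50
    tol: float = 1e-6
    var_init: float = 0.04
    var_floor: float = 0.005
    signal_floor: float = 1.0
    merge_radius: float = 0.5
    background_weight: float = 0.005
    max_cluster_var_x: float = 0.25
    hetso_otv_cut: float = -0.3
    otv_init_drop: float = 2.0


@dataclass
class ClassifyThresholds:
    """Six-way classification cuts (call rate in %, metric cuts at the
    standard array-QC defaults)."""

    cr_cut: float = 90.0
    fld_cut: float = 3.6
    hetso_cut: float = -0.1
    hetso_otv_cut: float = -0.3
    homro2_cut: float = 0.3
    homro3_cut: float = -0.9
    n_minor_allele_cut: int = 2


@dataclass
class ClusterModel:
    """Fitted per-variant mixture: one row per component in ``labels``."""

    labels: tuple
    centers: np.ndarray  # (K, 2) in (x, y)
    variances: np.ndarray  # (K, 2) diagonal
    weights: np.ndarray  # (K,)
    responsibilities: np.ndarray  # (n_samples, K)
    counts: np.ndarray  # called samples per component

    def present(self, label: str) -> bool:
        return label in self.labels and self.counts[self.labels.index(label)] > 0

    def center(self, label: str) -> np.ndarray:
        return self.centers[self.labels.index(label)]

    def var_x(self, label: str) -> float:
        return float(self.variances[self.labels.index(label), 0])

    def count(self, label: str) -> int:
        return int(self.counts[self.labels.index(label)])


def _em(pts, mu, var, weights, log_prior_adj, max_iter, tol, var_floor,
        bg_logdens=None):
    """Diagonal-covariance Gaussian mixture EM with per-sample additive
    log-prior adjustments (renormalized per sample) and an optional uniform
    background component for outliers (fixed density ``exp(bg_logdens)``
    and fixed mixing weight, appended as the last column).  Returns the
    fitted Gaussian parameters, full weights, responsibilities and final
    log-likelihood."""
    n, k = pts.shape[0], mu.shape[0]
    mu = mu.copy()
    var = var.copy()
    w = weights.copy()
    k_all = k + (1 if bg_logdens is not None else 0)
    prev_ll = -np.inf
    ll = -np.inf
    r = np.full((n, k_all), 1.0 / k_all)
    for _ in range(max_iter):
        logw = np.log(np.maximum(w, 1e-12))[None, :]
        if log_prior_adj is not None:
            adj = log_prior_adj
            if bg_logdens is not None:
                adj = np.concatenate([adj, np.zeros((n, 1))], axis=1)
            logw = logw + adj
            logw = logw - logsumexp(logw, axis=1, keepdims=True)
        logp = -0.5 * (
            ((pts[:, None, :] - mu[None, :, :]) ** 2) / var[None, :, :]
            + np.log(2.0 * np.pi * var[None, :, :])
        ).sum(axis=2)
        if bg_logdens is not None:
            logp = np.concatenate([logp, np.full((n, 1), bg_logdens)], axis=1)
        joint = logp + logw
        ll = float(logsumexp(joint, axis=1).sum())
        r = softmax(joint, axis=1)
        nk = r.sum(axis=0)
        if bg_logdens is not None:
            # background keeps its fixed weight; Gaussians share the rest
            bgw = w[-1]
            wg = np.maximum(nk[:k], 1e-12)
            w = np.append(wg / wg.sum() * (1.0 - bgw), bgw)
        else:
            w = np.maximum(nk, 1e-12) / n
            w = w / w.sum()
        occupied = nk[:k] > 1e-6
        if occupied.any():
            rg = r[:, :k]
            mu_new = mu.copy()
            var_new = var.copy()
            mu_new[occupied] = (rg.T @ pts)[occupied] / nk[:k][occupied, None]
            diff2 = (pts[:, None, :] - mu_new[None, :, :]) ** 2
            var_new[occupied] = np.maximum(
                (rg[:, :, None] * diff2).sum(axis=0)[occupied] / nk[:k][occupied, None],
                var_floor,
            )
            mu, var = mu_new, var_new
        if abs(ll - prev_ll) < tol * max(1.0, abs(prev_ll)):
            break
        prev_ll = ll
    return mu, var, w, r, ll


def _merge_components(mu, var, w, r, radius):
    """Absorb components whose centers coincide (within ``radius`` in the
    (x, y) plane) into the heavier component."""
    keep = list(range(mu.shape[0]))
    changed = True
    while changed:
        changed = False
        order = sorted(keep, key=lambda i: -w[i])
        for a, b in combinations(order, 2):
            if np.hypot(*(mu[a] - mu[b])) < radius:
                r[:, a] += r[:, b]
                w[a] += w[b]
                keep.remove(b)
                changed = True
                break
    idx = sorted(keep, key=lambda i: -mu[i, 0])  # descending contrast
    return mu[idx], var[idx], w[idx], r[:, idx]


def _label_by_position(mu_x, prior_delta):
    """Assign genotype labels to contrast-sorted components.

    Chooses the contrast-ordered subsequence of (AA, AB, BB) that minimizes
    the total distance to the a-priori centers (+delta, 0, -delta), so a
    lone cluster at +delta is AA, a pair at (+delta, 0) is (AA, AB), and a
    full triplet is (AA, AB, BB) regardless of global shifts.
    """
    prior = {"AA": prior_delta, "AB": 0.0, "BB": -prior_delta}
    k = len(mu_x)
    best, best_cost = None, np.inf
    for subset in combinations(("AA", "AB", "BB"), k):
        cost = sum(abs(x - prior[lbl]) for x, lbl in zip(mu_x, subset))
        if cost < best_cost:
            best, best_cost = subset, cost
    return list(best)


def _split_low_size(y, min_range: float = 1.5):
    """Split samples into a low-size and a high-size group at the midpoint
    of the size range when the range is wide enough to suggest an
    off-target cloud; returns (low_mask, high_mask) or (None, None)."""
    y = np.asarray(y, float)
    if np.ptp(y) <= min_range:
        return None, None
    tau = (y.min() + y.max()) / 2.0
    low = y <= tau
    if not low.any() or low.all():
        return None, None
    return low, ~low


def _bg_logdens(x, y, params):
    if params.background_weight <= 0:
        return None
    area = (np.ptp(x) + 0.5) * (np.ptp(y) + 0.5)
    return float(-np.log(area))


def _finalize(mu, var, w, r, labels, confidence_min):
    """Emit calls from responsibilities ``r`` whose columns are the labeled
    Gaussian components, optionally followed by one background column;
    background-dominated samples become no-calls."""
    k = len(labels)
    conf = r.max(axis=1)
    comp = r.argmax(axis=1)
    codes = np.array(
        [_LABEL_CODE[lbl] for lbl in labels] + [MISSING] * (r.shape[1] - k),
        dtype=np.int8,
    )
    calls = codes[comp]
    calls[conf < confidence_min] = MISSING
    counts = np.array([(calls == _LABEL_CODE[lbl]).sum() for lbl in labels])
    model = ClusterModel(tuple(labels), mu, var, w[:k], r[:, :k], counts)
    return calls, conf, model


def _split_bg(w, r, has_bg):
    n = r.shape[0]
    if has_bg:
        return r[:, :-1], r[:, -1:], w[:-1], w[-1:]
    return r, np.zeros((n, 0)), w, w[:0]


def _refit_merged(pts, mu, var, w_g, bgw, adj_term, params, bgld, d):
    """Short EM refinement from merged parameters, with the het-prior
    adjustment re-targeted at the component that will be labeled AB."""
    n = pts.shape[0]
    k = mu.shape[0]
    labels = _label_by_position(mu[:, 0], d)
    adj = np.zeros((n, k))
    if "AB" in labels:
        adj[:, labels.index("AB")] = adj_term
    w0 = w_g / max(w_g.sum(), 1e-12) * (1.0 - bgw)
    if bgld is not None:
        w0 = np.append(w0, bgw)
    return _em(pts, mu, var, w0, adj, 15, params.tol, params.var_floor, bgld)


def call_genotypes(
    x: np.ndarray,
    y: np.ndarray,
    penalties: np.ndarray | None = None,
    params: ClusterParams | None = None,
) -> tuple[np.ndarray, np.ndarray, ClusterModel]:
    """EM genotype calling for one variant.

    Three starts are tried — the generic a-priori centers, a contrast-
    quantile start, and a start seeding the heterozygote component at the
    low-size cloud (off-target geometry) — each followed by merging of
    coincident components and a short refinement; the refined fit with the
    highest likelihood wins.  Returns (calls, confidences, model); calls
    use array-space codes with ``MISSING`` where the maximum posterior
    falls below ``confidence_min`` or where the uniform background / an
    overly broad junk component wins (scattered points that belong to no
    genotype cluster).
    """
    params = params or ClusterParams()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 2:
        raise ValidationError("at least 2 samples are required for calling")
    penalties = np.zeros(n) if penalties is None else np.asarray(penalties, float)

    pts = np.stack([x, y], axis=1)
    y0 = float(np.median(y))
    d, off = params.contrast_delta, params.het_size_offset
    adj_term = -penalties / 2.0 * np.log(2.0)  # het prior x 2^(-penalty/2)

    bgld = _bg_logdens(x, y, params)
    bgw = params.background_weight if bgld is not None else 0.0
    init_a = np.array([[d, y0], [0.0, y0 + off], [-d, y0]])
    q_hi, q_lo = np.quantile(x, [0.9, 0.1])
    init_b = np.stack(
        [np.array([q_hi, (q_hi + q_lo) / 2.0, q_lo]), np.full(3, y0)], axis=1
    )
    low, high = _split_low_size(y)
    if low is not None:
        y_hi = float(np.median(y[high]))
        init_c = np.array(
            [
                [d, y_hi],
                [float(np.median(x[low])), float(np.median(y[low]))],
                [-d, y_hi],
            ]
        )
    else:
        init_c = init_a
    var0 = np.full((3, 2), params.var_init)
    w0 = np.full(3, (1.0 - bgw) / 3.0)
    if bgld is not None:
        w0 = np.append(w0, bgw)
    adj0 = np.zeros((n, 3))
    adj0[:, 1] = adj_term

    best = None
    for init in (init_a, init_b, init_c):
        mu, var, w, r, _ = _em(pts, init, var0, w0, adj0, params.max_iter,
                               params.tol, params.var_floor, bgld)
        r_g, _, w_g, _ = _split_bg(w, r, bgld is not None)
        mu, var, w_g, _ = _merge_components(mu, var, w_g, r_g, params.merge_radius)
        fit = _refit_merged(pts, mu, var, w_g, bgw, adj_term, params, bgld, d)
        if best is None or fit[4] > best[4] + 1e-9:
            best = fit
    mu, var, w, r, _ = best

    r_g, r_bg, w_g, w_bg = _split_bg(w, r, bgld is not None)
    order = np.argsort(-mu[:, 0], kind="stable")  # descending contrast
    mu, var, w_g, r_g = mu[order], var[order], w_g[order], r_g[:, order]
    # overly broad components are junk, not genotype clusters: their members
    # become no-calls (like the background)
    good = (var[:, 0] <= params.max_cluster_var_x) & (
        var[:, 1] <= params.max_cluster_var_x
    )
    labels = _label_by_position(mu[good, 0], d)
    r_full = np.concatenate([r_g[:, good], r_g[:, ~good], r_bg], axis=1)
    w_full = np.concatenate([w_g[good], w_g[~good], w_bg])
    return _finalize(mu[good], var[good], w_full, r_full, labels,
                     params.confidence_min)


def detect_otv(
    x: np.ndarray,
    y: np.ndarray,
    fitted: ClusterModel,
    penalties: np.ndarray | None = None,
    params: ClusterParams | None = None,
) -> tuple[np.ndarray, np.ndarray, ClusterModel, bool]:
    """Re-call a variant with an additional low-size OO cluster.

    Intended for variants whose HetSO falls below the OTV cut: a fourth
    component is initialized below the homozygote centers (seeded at the
    low-size tail of the data) and samples assigned to it receive genotype
    OO.  Returns (calls, confidences, model, degenerate); ``degenerate`` is
    set when every sample lands in the OO cluster.
    """
    params = params or ClusterParams()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    penalties = np.zeros(n) if penalties is None else np.asarray(penalties, float)

    if not any(fitted.present(lbl) for lbl in ("AA", "BB")):
        # no homozygote reference cluster: the whole variant is one low-size
        # cloud, so every sample is an off-target carrier
        calls = np.full(n, OO, dtype=np.int8)
        conf = np.ones(n)
        model = ClusterModel(
            ("OO",),
            np.array([[float(np.median(x)), float(np.median(y))]]),
            np.array([[params.var_init, params.var_init]]),
            np.ones(1), np.ones((n, 1)), np.array([n]),
        )
        return calls, conf, model, True

    d, off = params.contrast_delta, params.het_size_offset
    low, high = _split_low_size(y)
    if low is not None:
        y_hi = float(np.median(y[high]))
        oo_init = np.array(
            [float(np.median(x[low])), float(np.median(y[low]))]
        )
    else:
        y_hi = float(np.median(y))
        base_y = min(
            [fitted.center(lbl)[1] for lbl in ("AA", "BB") if lbl in fitted.labels],
            default=y_hi,
        )
        oo_init = np.array([0.0, base_y - params.otv_init_drop])

    def _hom(lbl, default_x):
        if lbl in fitted.labels:
            return fitted.center(lbl)
        return np.array([default_x, y_hi])

    # AA/BB seeded from the primary fit, AB back at its generic position
    # (the primary AB component may have been dragged onto the OO cloud),
    # OO at the low-size cloud
    mu0 = np.vstack(
        [_hom("AA", d), np.array([0.0, y_hi + off]), _hom("BB", -d), oo_init]
    )
    var0 = np.full((4, 2), params.var_init)
    k = mu0.shape[0]
    bgld = _bg_logdens(x, y, params)
    bgw = params.background_weight if bgld is not None else 0.0
    w0 = np.full(k, (1.0 - bgw) / k)
    if bgld is not None:
        w0 = np.append(w0, bgw)
    adj = np.zeros((n, k))
    adj[:, 1] = -penalties / 2.0 * np.log(2.0)

    pts = np.stack([x, y], axis=1)
    mu, var, w, r, _ = _em(pts, mu0, var0, w0, adj,
                           params.max_iter, params.tol, params.var_floor, bgld)

    # the OO cluster is the lowest-size component; the rest are labeled by
    # contrast position as in the primary fit (overly broad components are
    # junk and their members become no-calls)
    oo_idx = int(np.argmin(mu[:, 1]))
    rest = [i for i in range(k) if i != oo_idx]
    rest.sort(key=lambda i: -mu[i, 0])
    good = [i for i in rest if max(var[i, 0], var[i, 1]) <= params.max_cluster_var_x]
    junk = [i for i in rest if max(var[i, 0], var[i, 1]) > params.max_cluster_var_x]
    order = good + [oo_idx]
    extra = junk + list(range(k, r.shape[1]))  # junk, then background
    mu_o, var_o = mu[order], var[order]
    w_o = np.concatenate([w[order], w[extra]])
    r_o = r[:, order + extra]
    labels = _label_by_position(mu_o[:-1, 0], params.contrast_delta) + ["OO"]
    calls, conf, model = _finalize(mu_o, var_o, w_o, r_o, labels,
                                   params.confidence_min)
    degenerate = bool((calls == OO).all())
    return calls, conf, model, degenerate


# ---------------------------------------------------------------------------
# cluster metrics
# ---------------------------------------------------------------------------


def _pooled_sd(model: ClusterModel, labels: list[str]) -> float:
    ns = np.array([model.count(lbl) for lbl in labels], float)
    vs = np.array([model.var_x(lbl) for lbl in labels])
    if ns.sum() == 0:
        return float("nan")
    return float(np.sqrt((ns * vs).sum() / ns.sum()))


def fld(model: ClusterModel) -> float | None:
    """Contrast separation of AB from its nearest homozygote cluster, in
    pooled within-cluster standard deviations; None when AB or both
    homozygotes are absent."""
    if not model.present("AB"):
        return None
    homs = [lbl for lbl in ("AA", "BB") if model.present(lbl)]
    if not homs:
        return None
    x_ab = model.center("AB")[0]
    nearest = min(homs, key=lambda lbl: abs(model.center(lbl)[0] - x_ab))
    s = _pooled_sd(model, ["AB", nearest])
    if not np.isfinite(s) or s == 0:
        return None
    return float(abs(x_ab - model.center(nearest)[0]) / s)


def hom_fld(model: ClusterModel) -> float | None:
    """FLD analogue between the two homozygote clusters."""
    if not (model.present("AA") and model.present("BB")):
        return None
    s = _pooled_sd(model, ["AA", "BB"])
    if not np.isfinite(s) or s == 0:
        return None
    return float(abs(model.center("AA")[0] - model.center("BB")[0]) / s)


def het_so(model: ClusterModel) -> float | None:
    """Size offset of the AB center from the line through the AA and BB
    centers (or from the single present homozygote's size); negative values
    mean the heterozygote cluster sits below the homozygotes, the signature
    of off-target hybridization."""
    if not model.present("AB"):
        return None
    x_ab, y_ab = model.center("AB")
    has_aa, has_bb = model.present("AA"), model.present("BB")
    if has_aa and has_bb:
        (x_a, y_a), (x_b, y_b) = model.center("AA"), model.center("BB")
        if x_a == x_b:
            return float(y_ab - (y_a + y_b) / 2.0)
        y_line = y_a + (y_b - y_a) * (x_ab - x_a) / (x_b - x_a)
        return float(y_ab - y_line)
    if has_aa or has_bb:
        hom = "AA" if has_aa else "BB"
        return float(y_ab - model.center(hom)[1])
    return None


def hom_ro(model: ClusterModel) -> float | None:
    """Minimum signed distance of the present homozygote centers from zero
    contrast in their expected direction (+x for AA, -x for BB); positive
    when homozygote clusters sit on their expected sides."""
    vals = []
    if model.present("AA"):
        vals.append(model.center("AA")[0])
    if model.present("BB"):
        vals.append(-model.center("BB")[0])
    if not vals:
        return None
    return float(min(vals))


@dataclass
class ClusterMetrics:
    """Per-variant quality metrics feeding classification."""

    call_rate: float  # percent of samples with a call (OO counts as a call)
    fld: float | None
    hom_fld: float | None
    het_so: float | None
    hom_ro: float | None
    n_minor_allele: int
    n_geno_clusters: int  # AA/AB/BB clusters with at least one call
    n_samples: int


def cluster_metrics(model: ClusterModel, calls: np.ndarray) -> ClusterMetrics:
    calls = np.asarray(calls)
    n = calls.size
    called = calls != MISSING
    n_aa = int((calls == AA).sum())
    n_ab = int((calls == AB).sum())
    n_bb = int((calls == BB).sum())
    count_a = 2 * n_aa + n_ab
    count_b = 2 * n_bb + n_ab
    return ClusterMetrics(
        call_rate=100.0 * called.sum() / n,
        fld=fld(model),
        hom_fld=hom_fld(model),
        het_so=het_so(model),
        hom_ro=hom_ro(model),
        n_minor_allele=int(min(count_a, count_b)),
        n_geno_clusters=int((n_aa > 0) + (n_ab > 0) + (n_bb > 0)),
        n_samples=n,
    )


def classify(
    metrics: ClusterMetrics, thresholds: ClassifyThresholds | None = None
) -> str:
    """Deterministic six-way classification.

    Order: (1) one genotype cluster -> MonoHighResolution if metrics pass,
    else Other; (2) call rate below the cut -> CallRateBelowThreshold;
    (3) HetSO below the OTV cut -> OTV, other metric failures -> Other;
    (4) polymorphic without a minor-allele homozygote or with too few minor
    alleles -> NoMinorHom; (5) PolyHighResolution.
    """
    t = thresholds or ClassifyThresholds()
    m = metrics
    if m.n_geno_clusters <= 1:
        homro_ok = m.hom_ro is None or m.hom_ro > t.homro2_cut
        return "MonoHighResolution" if (m.call_rate >= t.cr_cut and homro_ok) else "Other"
    if m.call_rate < t.cr_cut:
        return "CallRateBelowThreshold"
    if m.het_so is not None and m.het_so < t.hetso_otv_cut:
        return "OTV"
    homro_cut = t.homro2_cut if m.n_geno_clusters == 2 else t.homro3_cut
    if m.hom_ro is not None and m.hom_ro < homro_cut:
        return "Other"
    if m.fld is not None and m.fld < t.fld_cut:
        return "Other"
    if m.het_so is not None and m.het_so < t.hetso_cut:
        return "Other"
    has_both_homs = m.n_geno_clusters == 3 or (
        m.n_geno_clusters == 2 and m.fld is None  # AA + BB without AB
    )
    if not has_both_homs or m.n_minor_allele < t.n_minor_allele_cut:
        return "NoMinorHom"
    return "PolyHighResolution"


# ---------------------------------------------------------------------------
# per-variant and panel-level drivers
# ---------------------------------------------------------------------------


@dataclass
class VariantResult:
    calls: np.ndarray
    confidences: np.ndarray
    model: ClusterModel
    metrics: ClusterMetrics
    category: str
    otv_recalled: bool = False
    degenerate: bool = False


def call_variant(
    x: np.ndarray,
    y: np.ndarray,
    penalties: np.ndarray | None = None,
    params: ClusterParams | None = None,
    thresholds: ClassifyThresholds | None = None,
) -> VariantResult:
    """Fit, measure, classify, and (for OTV geometry) re-call one variant.

    OTV re-calling is triggered by the classification itself (HetSO below
    the OTV cut), but also when a strongly negative HetSO was masked by a
    call-rate failure, or when no-call samples sit well below the fitted
    clusters in size — both signatures of an off-target cloud that the
    three-cluster fit could not accommodate.  After re-calling, the
    category is settled from the recalled calls: OTV when a distinct OO
    cluster exists and the call rate recovers, CallRateBelowThreshold when
    it does not.
    """
    params = params or ClusterParams()
    t = thresholds or ClassifyThresholds()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    calls, conf, model = call_genotypes(x, y, penalties, params)
    metrics = cluster_metrics(model, calls)
    category = classify(metrics, t)

    hetso_low = metrics.het_so is not None and metrics.het_so < t.hetso_otv_cut
    present_y = [model.center(lbl)[1] for lbl in ("AA", "AB", "BB")
                 if model.present(lbl)]
    low_missing = bool(
        present_y
        and ((calls == MISSING) & (y < min(present_y) - 1.0)).any()
    )
    otv_recalled = False
    degenerate = False
    if category == "OTV" or (
        category in ("CallRateBelowThreshold", "PolyHighResolution",
                     "NoMinorHom", "MonoHighResolution")
        and (hetso_low or low_missing)
    ):
        calls, conf, model, degenerate = detect_otv(x, y, model, penalties, params)
        otv_recalled = True
        final_cr = 100.0 * (calls != MISSING).mean()
        has_oo = bool((calls == OO).any())
        if has_oo and final_cr >= t.cr_cut:
            category = "OTV"
        elif has_oo and final_cr < t.cr_cut:
            category = "CallRateBelowThreshold"
        # without any OO member the original category stands
    return VariantResult(calls, conf, model, metrics, category, otv_recalled, degenerate)


@dataclass
class PanelCallResult:
    """Panel-level calls (samples x variants, array-space codes) plus the
    per-variant metrics/category table."""

    calls: np.ndarray
    confidences: np.ndarray
    variant_ids: list[str]
    samples: list[str]
    metrics: pd.DataFrame

    @property
    def call_rate_per_sample(self) -> np.ndarray:
        return 100.0 * (self.calls != MISSING).mean(axis=1)

    def categories(self) -> pd.Series:
        return self.metrics.set_index("variant_id")["category"]


def genotype_panel(
    intensities: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    inbred_correction: bool = True,
    params: ClusterParams | None = None,
    thresholds: ClassifyThresholds | None = None,
) -> PanelCallResult:
    """Call genotypes for every variant in a long intensity table.

    ``sample_sheet`` provides the sample order and the per-sample inbred
    penalties; with ``inbred_correction=False`` all penalties are zero.
    """
    params = params or ClusterParams()
    samples = sample_sheet["id"].tolist()
    pen = (
        sample_sheet["inbred_penalty"].to_numpy(float)
        if inbred_correction
        else np.zeros(len(samples))
    )

    wide_a = intensities.pivot(index="variant_id", columns="sample_id", values="signal_A")
    wide_b = intensities.pivot(index="variant_id", columns="sample_id", values="signal_B")
    missing = [s for s in samples if s not in wide_a.columns]
    if missing:
        raise ValidationError(f"samples missing from intensity table: {missing[:5]}")
    wide_a = wide_a[samples]
    wide_b = wide_b[samples]
    variant_ids = wide_a.index.tolist()

    x_all, y_all = transform(wide_a.to_numpy(), wide_b.to_numpy(), params.signal_floor)

    n_var, n_smp = x_all.shape
    calls = np.full((n_smp, n_var), MISSING, dtype=np.int8)
    confs = np.zeros((n_smp, n_var))
    rows = []
    for j in range(n_var):
        res = call_variant(x_all[j], y_all[j], pen, params, thresholds)
        calls[:, j] = res.calls
        confs[:, j] = res.confidences
        m = res.metrics
        rows.append(
            (
                variant_ids[j], m.call_rate, m.fld, m.hom_fld, m.het_so, m.hom_ro,
                m.n_minor_allele, m.n_geno_clusters, res.category,
                res.otv_recalled, res.degenerate,
                100.0 * (res.calls != MISSING).mean(),
            )
        )
    metrics = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "call_rate", "fld", "hom_fld", "het_so", "hom_ro",
            "n_minor_allele", "n_geno_clusters", "category",
            "otv_recalled", "degenerate", "final_call_rate",
        ],
    )
    return PanelCallResult(calls, confs, variant_ids, samples, metrics)


# ---------------------------------------------------------------------------
# correction comparison and class weights
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transition:
    before: str  # category without inbred correction
    after: str  # category with inbred correction

    @property
    def stable(self) -> bool:
        return self.before == self.after

    @property
    def promotion(self) -> bool:
        return (not self.stable) and self.after == "PolyHighResolution"


def compare_correction(category_without: str, category_with: str) -> Transition:
    """Ordered category pair with a stability flag, feeding the ranking."""
    for c in (category_without, category_with):
        if c not in CATEGORIES:
            raise ValidationError(f"unknown category {c!r}")
    return Transition(category_without, category_with)


def class_weight(transition: Transition) -> int:
    """Voting-system class weight: 10 for OTV-stable variants and for
    NoMinorHom promoted to PolyHighResolution by inbred correction; 5 for
    any other class promoted to PolyHighResolution; 0 otherwise."""
    if transition.before == "OTV" and transition.after == "OTV":
        return 10
    if transition.before == "NoMinorHom" and transition.after == "PolyHighResolution":
        return 10
    if transition.after == "PolyHighResolution" and transition.before != "PolyHighResolution":
        return 5
    return 0
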