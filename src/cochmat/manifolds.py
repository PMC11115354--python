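"""Mean-field-theoretic manifold analysis (MFTMA) of layer activations.

Each word class's set of activation vectors in a layer is treated as a
"manifold" — the convex hull of the population responses elicited by that
class.  Mean-field theory for the linear classification of general manifolds
yields, per class, an effective anchor dimensionality D_M, an anchor radius
R_M (extent relative to centroid distance), and a classification capacity
alpha_C: the number of class manifolds per neuron that a linear readout can
separate from all competitors.  For zero-extent (point) manifolds at zero
margin, alpha_C reduces to the classical perceptron capacity of 2.

The algorithm, per class manifold:

1. center the data globally, express each exemplar in the span of the
   manifold (D intra-manifold axes) plus one centroid direction, scaled by
   the centroid norm, giving points ``s`` in D+1 dimensions whose last
   coordinate is 1;
2. for each of ``n_t`` Gaussian direction samples ``t ~ N(0, I_{D+1})``,
   project ``t`` onto the polar cone ``{v : v . s_i + kappa <= 0}`` by a
   nonnegative least-squares subproblem; the residual ``t - v`` points at the
   manifold's "anchor point" (the unique convex combination of exemplars
   touching the margin plane), and ``||t - v||^2`` is the sample's
   contribution to the inverse capacity;
3. D_M is the mean squared alignment of ``t`` with the anchor's
   intra-manifold direction, R_M the root-mean-square intra-manifold anchor
   norm, and the layer capacity is the inverse mean of per-class inverse
   capacities.

A brute-force validation oracle estimates capacity directly: bisection over
the number of neurons, testing linear separability (through the origin) of
random +/-1 class dichotomies with a feasibility linear program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog, nnls

from ._seeds import substream

__all__ = [
    "MFTMAConfig",
    "ManifoldGeometry",
    "prepare_manifolds",
    "mftma",
    "separability_oracle",
    "layer_trajectory",
]


@dataclass(frozen=True)
class MFTMAConfig:
    """Algorithm constants for the mean-field manifold analysis."""

    kappa: float = 0.0  # classification margin
    n_gaussian_samples: int = 300
    random_projection_dim: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.n_gaussian_samples < 100:
            raise ValueError("need at least 100 Gaussian direction samples")


@dataclass
class ManifoldGeometry:
    """Per-layer manifold statistics (per-class values retained)."""

    layers: list[str]
    dimension: dict[str, float]  # layer -> mean D_M
    radius: dict[str, float]  # layer -> mean R_M
    capacity: dict[str, float]  # layer -> alpha_C
    per_class: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "layer": self.layers,
                "D_M": [self.dimension[l] for l in self.layers],
                "R_M": [self.radius[l] for l in self.layers],
                "capacity": [self.capacity[l] for l in self.layers],
            }
        )


def prepare_manifolds(activations, config: MFTMAConfig | None = None) -> dict[str, list[np.ndarray]]:
    """Group activation rows by class; random-project if the layer is wide.

    ``activations`` is a :class:`cochmat.training.ActivationSet`.  Layers with
    more features than ``random_projection_dim`` are projected with a seeded
    Gaussian map scaled by 1/sqrt(d) (approximately distance preserving);
    narrower layers pass through unchanged.  Returns, per layer, one
    (M_c x N') float64 matrix per class, in sorted class order.
    """
    config = config or MFTMAConfig()
    classes = sorted(set(activations.labels))
    label_arr = np.asarray(activations.labels)
    counts = {c: int(np.sum(label_arr == c)) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"every class needs >= 2 exemplars, got {counts}")
    out: dict[str, list[np.ndarray]] = {}
    for layer in activations.layer_ids:
        X = np.asarray(activations.activations[layer], dtype=np.float64)
        n_feat = X.shape[1]
        if n_feat > config.random_projection_dim:
            rng = substream(config.seed, "projection", layer)
            P = rng.standard_normal((n_feat, config.random_projection_dim)) / np.sqrt(
                config.random_projection_dim
            )
            X = X @ P
        out[layer] = [X[label_arr == c] for c in classes]
    return out


def _class_geometry(points: np.ndarray, global_mean: np.ndarray, config: MFTMAConfig, rng):
    """Anchor statistics for one class manifold.

    Returns (D_M, R_M, inverse capacity).  ``points`` is (M, N).
    """
    X = points - global_mean
    centroid = X.mean(axis=0)
    c_norm = np.linalg.norm(centroid)
    if c_norm < 1e-12:
        raise np.linalg.LinAlgError("degenerate manifold: centroid at the global mean")
    Xc = X - centroid
    # orthonormal intra-manifold axes (rank D <= M-1)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = S > max(S.max(initial=0.0) * 1e-10, 1e-12)
    D = int(keep.sum())
    # canonical axis signs (largest feature-space loading positive) so the
    # frame, and hence every Gaussian-sample subproblem, is invariant to
    # exemplar ordering
    Vk = Vt[keep]
    signs = np.sign(Vk[np.arange(D), np.argmax(np.abs(Vk), axis=1)])
    signs[signs == 0] = 1.0
    coords = (U[:, keep] * S[keep] * signs) / c_norm  # (M, D) intra-manifold coords
    # points in D+1 dims; last coordinate is the (unit-scaled) centroid direction
    S1 = np.concatenate([coords, np.ones((coords.shape[0], 1))], axis=1)  # (M, D+1)
    kappa = config.kappa

    t_all = rng.standard_normal((config.n_gaussian_samples, D + 1))
    inv_cap = 0.0
    d_samples, r_samples = [], []
    for t in t_all:
        proj = S1 @ t
        if proj.max() + kappa <= 0:
            # t already in the polar cone: no margin violation; the touching
            # anchor is the exemplar of maximal projection
            anchor = S1[int(np.argmax(proj))]
        else:
            if kappa == 0.0:
                a, _ = nnls(S1.T, t)
            else:
                a = _nnls_margin(S1, t, kappa)
            v = t - S1.T @ a
            r = t - v
            inv_cap += float(r @ r)
            tot = a.sum()
            if tot <= 1e-12:
                anchor = S1[int(np.argmax(proj))]
            else:
                anchor = (S1.T @ a) / tot
        a_par, a0 = anchor[:-1], anchor[-1]
        nrm = np.linalg.norm(a_par)
        if nrm > 1e-12 and abs(a0) > 1e-12:
            d_samples.append(float((t[:-1] @ (a_par / nrm)) ** 2))
            r_samples.append(float(nrm / abs(a0)))
        else:
            d_samples.append(0.0)
            r_samples.append(0.0)
    inv_cap /= config.n_gaussian_samples
    D_M = float(np.mean(d_samples))
    R_M = float(np.sqrt(np.mean(np.square(r_samples))))
    return D_M, R_M, inv_cap


def _nnls_margin(S1: np.ndarray, t: np.ndarray, kappa: float) -> np.ndarray:
    """Dual of min ||v - t||^2 s.t. S1 v <= -kappa, solved as bounded QP."""
    from scipy.optimize import minimize

    G = S1 @ S1.T
    c = S1 @ t + kappa

    def f(a):
        Ga = G @ a
        return 0.5 * a @ Ga - a @ c, Ga - c

    M = S1.shape[0]
    res = minimize(f, np.zeros(M), jac=True, bounds=[(0, None)] * M, method="L-BFGS-B")
    return res.x


def mftma(class_matrices: list[np.ndarray], config: MFTMAConfig | None = None) -> dict:
    """Mean-field manifold statistics for one layer.

    ``class_matrices`` holds one (M_c x N) matrix per class, already prepared
    (projected) by :func:`prepare_manifolds`.  Returns per-class D_M, R_M and
    inverse capacities plus the layer capacity
    ``alpha_C = 1 / mean_c(1 / alpha_c)``.
    """
    config = config or MFTMAConfig()
    if len(class_matrices) < 2:
        raise ValueError("need at least two class manifolds")
    global_mean = np.concatenate(class_matrices, axis=0).mean(axis=0)
    rng = substream(config.seed, "mftma-directions")
    records = []
    for ci, X in enumerate(class_matrices):
        if X.shape[0] < 1:
            raise ValueError(f"class {ci} has no exemplars")
        try:
            D_M, R_M, inv_cap = _class_geometry(np.asarray(X, dtype=np.float64), global_mean, config, rng)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(f"class {ci}: {err}") from err
        records.append(dict(class_index=ci, D_M=D_M, R_M=R_M, inverse_capacity=inv_cap))
    per_class = pd.DataFrame(records)
    mean_inv = per_class["inverse_capacity"].mean()
    return {
        "per_class": per_class,
        "D_M": float(per_class["D_M"].mean()),
        "R_M": float(per_class["R_M"].mean()),
        "capacity": float(1.0 / mean_inv) if mean_inv > 0 else float("inf"),
    }


def _separable(points: np.ndarray, signs: np.ndarray) -> bool:
    """Feasibility LP: exists w with sign_i * (w . x_i) >= 1 for all i."""
    A_ub = -(signs[:, None] * points)
    res = linprog(
        c=np.zeros(points.shape[1]),
        A_ub=A_ub,
        b_ub=-np.ones(points.shape[0]),
        bounds=[(None, None)] * points.shape[1],
        method="highs",
    )
    return res.status == 0


def separability_oracle(
    class_matrices: list[np.ndarray],
    n_repeats: int = 20,
    seed: int = 0,
    n_grid: tuple[int, int] | None = None,
) -> float:
    """Empirical capacity: load P/N at 50% probability of linear separability.

    At a candidate neuron count ``n``, all points are randomly projected to
    ``n`` dimensions, each class is assigned a random +/-1 label, and an LP
    checks whether one homogeneous hyperplane separates every exemplar
    according to its class label; the separability probability over
    ``n_repeats`` dichotomies is monotone in ``n``.  Bisection locates the
    50% crossing and the capacity P/n* is linearly interpolated between the
    bracketing counts.  Intended for small instances (P * M <= 2000).
    """
    P = len(class_matrices)
    M_total = sum(X.shape[0] for X in class_matrices)
    if M_total > 2000:
        raise ValueError("oracle restricted to small instances (P*M <= 2000)")
    Xall = np.concatenate(class_matrices, axis=0).astype(np.float64)
    Xall = Xall - Xall.mean(axis=0)
    owners = np.concatenate([[i] * X.shape[0] for i, X in enumerate(class_matrices)])
    N = Xall.shape[1]
    rng = substream(seed, "oracle")

    def sep_prob(n: int) -> float:
        wins = 0
        for _ in range(n_repeats):
            proj = rng.standard_normal((N, n)) / np.sqrt(n)
            pts = Xall @ proj
            signs = rng.choice([-1.0, 1.0], size=P)[owners]
            wins += _separable(pts, signs)
        return wins / n_repeats

    lo, hi = n_grid if n_grid else (max(2, P // 8), min(N, 2 * P))
    p_lo, p_hi = sep_prob(lo), sep_prob(hi)
    if p_lo >= 0.5:
        return P / lo
    if p_hi < 0.5:
        return P / hi
    while hi - lo > 1:
        mid = (lo + hi) // 2
        p_mid = sep_prob(mid)
        if p_mid >= 0.5:
            hi, p_hi = mid, p_mid
        else:
            lo, p_lo = mid, p_mid
    # interpolate the 50% crossing between lo (p<0.5) and hi (p>=0.5)
    if p_hi == p_lo:
        n_star = hi
    else:
        n_star = lo + (0.5 - p_lo) / (p_hi - p_lo) * (hi - lo)
    return float(P / n_star)


def layer_trajectory(network, stimuli, labels, config: MFTMAConfig | None = None, layer_ids=None) -> ManifoldGeometry:
    """Manifold geometry across all probed layers of a network.

    ``stimuli`` are cochleagrams (blurred at the condition's test resolution
    upstream); geometry is computed per probed convolutional layer in forward
    order, so representational untangling can be read off the trajectory.
    """
    from .training import extract_activations

    config = config or MFTMAConfig()
    acts = extract_activations(network, stimuli, labels, layer_ids)
    prepared = prepare_manifolds(acts, config)
    layers = acts.layer_ids
    geom = ManifoldGeometry(layers=layers, dimension={}, radius={}, capacity={})
    for layer in layers:
        res = mftma(prepared[layer], config)
        geom.dimension[layer] = res["D_M"]
        geom.radius[layer] = res["R_M"]
        geom.capacity[layer] = res["capacity"]
        geom.per_class[layer] = res["per_class"]
    return geom
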