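"""Temporal trajectory clustering with a circular self-organizing map.

Gene expression is collapsed to one mean per age group and z-scored to a
4-point shape profile.  Shape similarity is the Pearson correlation of the
two profiles after linear interpolation onto a uniform grid over real age
(so the unequal spacing of 3/6/12/20 months is respected).  A 1-D circular
SOM groups and circularly orders the profiles; the cluster count is chosen
by minimizing a spherical-Gaussian BIC on the node assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "temporal_profiles",
    "coexpression_similarity",
    "som_cluster",
    "select_k_bic",
    "ClusterModel",
]

DEFAULT_AGES = (3, 6, 12, 20)


def temporal_profiles(log2cpm: pd.DataFrame, age_of: pd.Series, ages=DEFAULT_AGES):
    """Z-scored per-age mean profiles.

    Returns (profiles, constant_flag): genes x len(ages) z-profiles (mean 0,
    population sd 1) and a boolean Series marking constant (unclusterable)
    genes, whose profile rows are left as NaN.
    """
    means = []
    for age in ages:
        cols = age_of.index[age_of == age]
        if len(cols) == 0:
            raise ValueError(f"no samples for age group {age}")
        means.append(log2cpm[cols].mean(axis=1))
    m = pd.concat(means, axis=1)
    m.columns = list(ages)
    mu = m.mean(axis=1)
    sd = m.std(axis=1, ddof=0)
    constant = sd == 0
    z = m.sub(mu, axis=0).div(sd.where(~constant), axis=0)
    return z, constant


def _interp_operator(ages, grid_points: int) -> np.ndarray:
    """Linear map (grid_points x len(ages)) applying piecewise-linear
    interpolation of a profile onto a uniform age grid."""
    ages = np.asarray(ages, dtype=float)
    grid = np.linspace(ages[0], ages[-1], grid_points)
    w = np.zeros((grid_points, ages.size))
    for i, basis in enumerate(np.eye(ages.size)):
        w[:, i] = np.interp(grid, ages, basis)
    return w


def coexpression_similarity(
    profile_a,
    profile_b,
    ages=DEFAULT_AGES,
    grid_points: int = 101,
) -> float:
    """Pearson correlation of two linearly interpolated temporal profiles."""
    w = _interp_operator(ages, grid_points)
    xa, xb = w @ np.asarray(profile_a, float), w @ np.asarray(profile_b, float)
    if xa.std() == 0 or xb.std() == 0:
        raise ValueError("constant interpolated series")
    return float(np.corrcoef(xa, xb)[0, 1])


def _interp_corr_matrix(profiles: np.ndarray, nodes: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between interpolated profiles (rows) and
    interpolated nodes (rows); result is profiles x nodes."""
    pa = profiles @ w.T
    pb = nodes @ w.T
    pa = pa - pa.mean(axis=1, keepdims=True)
    pb = pb - pb.mean(axis=1, keepdims=True)
    na = np.linalg.norm(pa, axis=1)
    nb = np.linalg.norm(pb, axis=1)
    na[na == 0] = np.inf
    nb[nb == 0] = np.inf
    return (pa @ pb.T) / np.outer(na, nb)


@dataclass
class ClusterModel:
    k: int
    nodes: np.ndarray            # k x d ring of node profiles (circular order)
    assignment: pd.Series        # gene -> node index
    similarity: pd.Series        # gene -> similarity to its node
    bic: float

    def node_means(self, profiles: pd.DataFrame) -> np.ndarray:
        """Average member z-profile per node (the cluster's mean trajectory)."""
        out = np.full_like(self.nodes, np.nan)
        z = profiles.to_numpy(float)
        for c in range(self.k):
            members = self.assignment.to_numpy() == c
            if members.any():
                out[c] = z[members].mean(axis=0)
        return out


def _bic(profiles: np.ndarray, assign: np.ndarray, k: int) -> float:
    """Spherical-Gaussian BIC of the partition:
    n*d*ln(RSS/(n*d)) + k*d*ln(n), with RSS taken to the within-cluster mean
    profiles (the clusters' averaged temporal profiles) rather than the raw
    SOM node vectors, which the ring neighborhood keeps slightly coupled."""
    n, d = profiles.shape
    rss = 0.0
    for c in range(k):
        members = profiles[assign == c]
        if len(members):
            rss += float(np.sum((members - members.mean(axis=0)) ** 2))
    rss = max(rss, 1e-12)
    return n * d * np.log(rss / (n * d)) + k * d * np.log(n)


def som_cluster(
    profiles: pd.DataFrame,
    k: int,
    epochs: int = 200,
    lr_schedule: tuple[float, float] = (0.5, 0.01),
    ages=DEFAULT_AGES,
    grid_points: int = 101,
    seed: int = 0,
) -> ClusterModel:
    """Train a 1-D circular SOM on temporal profiles.

    Distance is 1 - co-expression similarity.  The neighborhood is Gaussian
    on ring distance with width decaying exponentially from k/2 to 0.5, the
    learning rate decays from ``lr_schedule[0]`` to ``lr_schedule[1]``, and
    node vectors are initialized by sampling profiles.  Deterministic given
    ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    z = profiles.to_numpy(dtype=float)
    n, d = z.shape
    if k > n:
        raise ValueError("more clusters than profiles")
    rng = np.random.default_rng(seed)
    w = _interp_operator(ages, grid_points)
    nodes = z[rng.choice(n, size=k, replace=False)].copy()
    # small jitter so duplicated seeds cannot freeze two nodes together
    nodes += rng.normal(0.0, 1e-3, size=nodes.shape)

    ring = np.arange(k)
    ring_dist = np.minimum(np.abs(ring[:, None] - ring[None, :]), k - np.abs(ring[:, None] - ring[None, :]))
    lr0, lr1 = lr_schedule
    sigma0, sigma1 = k / 2.0, 0.5
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        lr = lr0 * (lr1 / lr0) ** frac
        sigma = sigma0 * (sigma1 / sigma0) ** frac
        neigh = np.exp(-(ring_dist**2) / (2.0 * sigma**2))
        order = rng.permutation(n)
        sim = _interp_corr_matrix(z, nodes, w)
        for idx in order:
            bmu = int(np.argmax(sim[idx]))
            nodes += (lr * neigh[bmu][:, None]) * (z[idx] - nodes)
        # refresh similarities once per epoch (batch-style update accuracy)
    sim = _interp_corr_matrix(z, nodes, w)
    assign = np.argmax(sim, axis=1)
    model = ClusterModel(
        k=k,
        nodes=nodes,
        assignment=pd.Series(assign, index=profiles.index, name="cluster"),
        similarity=pd.Series(sim[np.arange(n), assign], index=profiles.index, name="similarity"),
        bic=_bic(z, assign, k),
    )
    return model


def select_k_bic(
    profiles: pd.DataFrame,
    k_range=range(2, 11),
    seed: int = 0,
    **som_kwargs,
):
    """Choose the cluster count by Gaussian-mixture BIC, then fit the SOM.

    Z-scored profiles are degenerate (mean 0 and fixed norm confine them to
    a sphere inside the profile space), which makes hard-assignment RSS
    criteria reward splitting pure noise.  The count is therefore selected
    by the BIC of a full-covariance Gaussian mixture fitted in the
    (d-1)-dimensional mean-zero coordinate system, where the soft EM
    likelihood is consistent; the circular SOM is then trained at the chosen
    k for grouping and ring ordering.

    Returns (k_star, {k: BIC}, ClusterModel at k_star).
    """
    from sklearn.mixture import GaussianMixture

    d = profiles.shape[1]
    # orthonormal basis of the mean-zero subspace
    basis = np.linalg.svd(np.eye(d) - np.full((d, d), 1.0 / d))[0][:, : d - 1]
    y = profiles.to_numpy(dtype=float) @ basis
    bics: dict[int, float] = {}
    for k in k_range:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            random_state=seed,
            n_init=5,
            reg_covar=1e-4,
        ).fit(y)
        bics[k] = float(gm.bic(y))
    k_star = min(bics, key=lambda k: (bics[k], k))
    model = som_cluster(profiles, k_star, seed=seed, **som_kwargs)
    return k_star, bics, model
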