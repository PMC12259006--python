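"""Figure-level ensemble analyses: primed/collapsed classification,
conditional distributions, free-energy landscapes, and self-labelling
autoencoder comparison of two ensembles with feature attribution.

The label model is a supervised autoencoder ("DiffNet"-style): an encoder
compresses centred heavy-atom coordinates to a low-dimensional latent space,
a decoder reconstructs them, and a scalar sigmoid head predicts a label in
[0, 1] interpreted as an activity coordinate.  Training alternates gradient
steps on (reconstruction MSE + label binary cross-entropy) with an
expectation-maximization-like update in which the targets are replaced by
the model's own label outputs clamped into per-ensemble bounds.  Structural
interpretation comes afterwards, by ranking inter-residue distances by their
Pearson correlation with the learned labels.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NoValleyError",
    "BundleClassification",
    "ConditionalSummary",
    "FreeEnergySurface",
    "LabelModelConfig",
    "LabelModel",
    "choose_cutoff",
    "classify_bundle",
    "conditional_distributions",
    "free_energy_surface",
    "train_label_model",
    "feature_label_correlation",
]


class NoValleyError(ValueError):
    """Density between modes has no valley (unimodal data); set a cutoff manually."""


# ---------------------------------------------------------------------------
# Primed / collapsed classification of bundle SASA
# ---------------------------------------------------------------------------

def choose_cutoff(values: np.ndarray, grid_size: int = 512) -> float:
    """Place the primed/collapsed cutoff at the density valley between modes.

    A Gaussian kernel density (Silverman bandwidth) is evaluated on the
    pooled values; the cutoff is the argmin of the density between the two
    highest modes.  Unimodal data raises :class:`NoValleyError`.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 100:
        raise ValueError("need at least 100 values to place a cutoff")
    if np.ptp(values) == 0:
        raise NoValleyError("all values identical; no valley to place a cutoff")
    kde = stats.gaussian_kde(values, bw_method="silverman")
    lo, hi = values.min(), values.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:])
    ) + 1
    if interior.size < 2:
        raise NoValleyError("density is unimodal; choose a cutoff manually")
    top2 = interior[np.argsort(dens[interior])[::-1][:2]]
    a, b = sorted(top2)
    valley = a + int(np.argmin(dens[a:b + 1]))
    return float(grid[valley])


@dataclass
class BundleClassification:
    """Per-sample bundle SASA with primed/collapsed labels and the cutoff used."""

    bundle_sasa: np.ndarray
    labels: np.ndarray  # 'primed' | 'collapsed'
    cutoff: float

    @property
    def primed_fraction(self) -> float:
        return float(np.mean(self.labels == "primed"))


def classify_bundle(bundle_sasa: np.ndarray, cutoff: float) -> BundleClassification:
    """Label samples primed (SASA strictly above cutoff) or collapsed (<=)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    v = np.asarray(bundle_sasa, dtype=np.float64)
    labels = np.where(v > cutoff, "primed", "collapsed")
    return BundleClassification(v, labels, float(cutoff))


# ---------------------------------------------------------------------------
# Conditional distributions
# ---------------------------------------------------------------------------

@dataclass
class ConditionalSummary:
    """Per-label histograms (shared edges) and summary statistics."""

    edges: np.ndarray
    histograms: dict[str, np.ndarray]
    summary: pd.DataFrame
    ks_statistic: float
    ks_pvalue: float


def conditional_distributions(
    values: np.ndarray,
    labels: np.ndarray,
    bins: int = 50,
    threshold: float = 2.5,
) -> ConditionalSummary:
    """Empirical distribution of ``values`` conditioned on a binary label.

    Reports per-label mean, median, and P(value < threshold) — the default
    threshold of 2.5 A is used as a "primed linchpin" probability when the
    values are linchpin RMSDs — plus the two-sample Kolmogorov-Smirnov
    statistic between the two groups.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        missing = [l for l in ("primed", "collapsed") if l not in uniq]
        raise ValueError(
            f"need exactly two label groups, got {uniq}"
            + (f" (missing {missing})" if missing else "")
        )
    edges = np.histogram_bin_edges(values, bins=bins)
    hists, rows, groups = {}, [], []
    for lab in uniq:
        v = values[labels == lab]
        groups.append(v)
        hists[lab] = np.histogram(v, bins=edges)[0]
        rows.append(
            {"label": lab, "n": v.size, "mean": v.mean(), "median": np.median(v),
             "p_below_threshold": float(np.mean(v < threshold))}
        )
    ks = stats.ks_2samp(groups[0], groups[1], method="asymp")
    return ConditionalSummary(
        edges, hists, pd.DataFrame(rows).set_index("label"),
        float(ks.statistic), float(ks.pvalue),
    )


# ---------------------------------------------------------------------------
# Free-energy landscape
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergySurface:
    """-ln(P / P_max) in kT over a 2-D distance grid; empty bins masked."""

    free_energy: np.ma.MaskedArray
    x_edges: np.ndarray
    y_edges: np.ndarray


def free_energy_surface(d1: np.ndarray, d2: np.ndarray, bins: int = 50) -> FreeEnergySurface:
    """Project equilibrium samples onto two coordinates as a free-energy map."""
    d1 = np.asarray(d1, dtype=np.float64)
    d2 = np.asarray(d2, dtype=np.float64)
    if d1.shape != d2.shape:
        raise ValueError("coordinate vectors differ in length")
    H, xe, ye = np.histogram2d(d1, d2, bins=bins)
    mask = H == 0
    with np.errstate(divide="ignore"):
        F = -np.log(H / H.max())
    return FreeEnergySurface(np.ma.MaskedArray(F, mask=mask), xe, ye)


# ---------------------------------------------------------------------------
# Self-labelling autoencoder
# ---------------------------------------------------------------------------

@dataclass
class LabelModelConfig:
    """Training configuration for the self-labelling autoencoder.

    ``em_bounds_a``/``em_bounds_b`` clamp the self-consistent label targets
    for each ensemble after every epoch; ``initial_labels`` seed the targets
    (defaults 0.5 for the putatively inactive ensemble and 1.0 for the
    active one).
    """

    em_bounds_a: tuple[float, float] = (0.2, 0.8)
    em_bounds_b: tuple[float, float] = (0.6, 0.8)
    initial_labels: tuple[float, float] = (0.5, 1.0)
    epochs: int = 50
    latent_dim: int = 10
    hidden_dim: int = 50
    batch_size: int = 256
    learning_rate: float = 3e-3
    label_weight: float = 3.0  # BCE weight vs per-element reconstruction MSE
    seed: int = 0

    def validate(self) -> None:
        for lo, hi in (self.em_bounds_a, self.em_bounds_b):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"EM bounds ({lo}, {hi}) must satisfy 0 <= lo <= hi <= 1")
        for v in self.initial_labels:
            if not 0.0 <= v <= 1.0:
                raise ValueError("initial labels must lie in [0, 1]")
        if self.epochs < 1 or self.latent_dim < 1 or self.hidden_dim < 1:
            raise ValueError("epochs, latent_dim and hidden_dim must be positive")


@dataclass
class LabelModel:
    """Trained label model: final per-frame labels and learned parameters."""

    labels: np.ndarray          # (n_a + n_b,) in [0, 1], A frames first
    n_a: int
    n_b: int
    config: LabelModelConfig
    params: dict[str, np.ndarray]
    feature_mean: np.ndarray
    feature_scale: np.ndarray

    @property
    def labels_a(self) -> np.ndarray:
        return self.labels[: self.n_a]

    @property
    def labels_b(self) -> np.ndarray:
        return self.labels[self.n_a:]

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=np.float64) - self.feature_mean) / self.feature_scale
        _, _, _, lab = _forward(Xs, self.params)
        return lab


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _forward(X: np.ndarray, p: dict[str, np.ndarray]):
    h1 = np.tanh(X @ p["We1"] + p["be1"])
    z = h1 @ p["We2"] + p["be2"]
    h2 = np.tanh(z @ p["Wd1"] + p["bd1"])
    recon = h2 @ p["Wd2"] + p["bd2"]
    label = _sigmoid(z @ p["Wl"] + p["bl"]).ravel()
    return (h1, z, h2), recon, z, label


def _init_params(d: int, hidden: int, latent: int, rng: np.random.Generator):
    def glorot(fan_in, fan_out):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, size=(fan_in, fan_out))

    return {
        "We1": glorot(d, hidden), "be1": np.zeros(hidden),
        "We2": glorot(hidden, latent), "be2": np.zeros(latent),
        "Wd1": glorot(latent, hidden), "bd1": np.zeros(hidden),
        "Wd2": glorot(hidden, d), "bd2": np.zeros(d),
        "Wl": glorot(latent, 1), "bl": np.zeros(1),
    }


def _grads(X, targets, p, label_weight):
    n, d = X.shape
    (h1, z, h2), recon, _, label = _forward(X, p)
    # reconstruction MSE (mean over elements) + BCE on the label head
    d_recon = 2.0 * (recon - X) / (n * d)
    d_label = (label - targets)[:, None] * (label_weight / n)

    g = {}
    g["Wd2"] = h2.T @ d_recon
    g["bd2"] = d_recon.sum(axis=0)
    d_h2 = d_recon @ p["Wd2"].T * (1.0 - h2**2)
    g["Wd1"] = z.T @ d_h2
    g["bd1"] = d_h2.sum(axis=0)
    g["Wl"] = z.T @ d_label
    g["bl"] = d_label.sum(axis=0)
    d_z = d_h2 @ p["Wd1"].T + d_label @ p["Wl"].T
    g["We2"] = h1.T @ d_z
    g["be2"] = d_z.sum(axis=0)
    d_h1 = d_z @ p["We2"].T * (1.0 - h1**2)
    g["We1"] = X.T @ d_h1
    g["be1"] = d_h1.sum(axis=0)
    return g


def train_label_model(
    frames_a: np.ndarray,
    frames_b: np.ndarray,
    config: LabelModelConfig | None = None,
) -> LabelModel:
    """Train the self-labelling autoencoder on two conformational ensembles.

    ``frames_a`` and ``frames_b`` are ``(n, d)`` matrices of flattened,
    reference-aligned coordinates (or any per-frame feature vectors); the
    ensembles must be disjoint.  Features are standardized internally.
    Deterministic under ``config.seed``.
    """
    config = config or LabelModelConfig()
    config.validate()
    Xa = np.asarray(frames_a, dtype=np.float64)
    Xb = np.asarray(frames_b, dtype=np.float64)
    if Xa.ndim != 2 or Xb.ndim != 2 or Xa.shape[1] != Xb.shape[1]:
        raise ValueError("ensembles must be 2-D with a common feature dimension")
    seen = {row.tobytes() for row in Xa}
    if any(row.tobytes() in seen for row in Xb):
        raise ValueError("ensembles overlap: identical frames found in both")

    X = np.vstack([Xa, Xb])
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    n_a, n_b = Xa.shape[0], Xb.shape[0]
    n = n_a + n_b
    is_b = np.zeros(n, dtype=bool)
    is_b[n_a:] = True

    rng = np.random.default_rng(config.seed)
    p = _init_params(X.shape[1], config.hidden_dim, config.latent_dim, rng)
    m = {k: np.zeros_like(v) for k, v in p.items()}
    v = {k: np.zeros_like(v) for k, v in p.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0

    targets = np.where(is_b, config.initial_labels[1], config.initial_labels[0]).astype(float)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            g = _grads(Xs[batch], targets[batch], p, config.label_weight)
            step += 1
            for k in p:
                m[k] = b1 * m[k] + (1 - b1) * g[k]
                v[k] = b2 * v[k] + (1 - b2) * g[k] ** 2
                mh = m[k] / (1 - b1**step)
                vh = v[k] / (1 - b2**step)
                p[k] -= config.learning_rate * mh / (np.sqrt(vh) + eps)
        # EM step: self-consistent targets, clamped into per-ensemble bounds
        _, _, _, raw = _forward(Xs, p)
        targets = np.where(
            is_b,
            np.clip(raw, config.em_bounds_b[0], config.em_bounds_b[1]),
            np.clip(raw, config.em_bounds_a[0], config.em_bounds_a[1]),
        )

    _, _, _, final = _forward(Xs, p)
    return LabelModel(final, n_a, n_b, config, p, mean, scale)


def feature_label_correlation(
    distances: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each distance column with the labels.

    Returns a DataFrame ranked by |r| (descending, sign retained);
    zero-variance columns get ``r = NaN`` and sort last.
    """
    D = np.asarray(distances, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64).ravel()
    if D.ndim != 2 or D.shape[0] != y.size:
        raise ValueError("distances must be (n_frames, n_features) matching labels")
    if np.unique(y).size < 2:
        raise ValueError("labels are constant; correlation undefined")
    yc = y - y.mean()
    Dc = D - D.mean(axis=0)
    sd = Dc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Dc.T @ yc) / (D.shape[0] * sd * yc.std())
    r[sd == 0] = np.nan
    names = feature_names or [f"d{i}" for i in range(D.shape[1])]
    df = pd.DataFrame({"feature": names, "r": r, "abs_r": np.abs(r)})
    df = df.sort_values("abs_r", ascending=False, na_position="last")
    return df.drop(columns="abs_r").reset_index(drop=True)
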