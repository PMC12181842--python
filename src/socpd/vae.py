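"""Variational autoencoder for latent phenotyping of tabular features.

A small fully connected VAE compresses 11 standardized baseline
features (clinical scales, the glymphatic ALPS index, a risk-allele
dosage count, age) into a 2-dimensional latent space. The encoder is
11 -> 16 (ReLU) -> 4, the four outputs supplying 2 latent means and 2
log-variances; the decoder mirrors the encoder with a linear output.
Training minimizes the negative evidence lower bound (Gaussian
reconstruction with unit variance plus the KL divergence of the
approximate posterior from a standard normal prior) with the
reparameterization trick and the Adam optimizer. Implemented directly
in numpy with hand-derived gradients; training is deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "VAEConfig",
    "VAEModel",
    "build_feature_table",
    "train_vae",
    "embed",
    "embed_and_compare",
    "DEFAULT_FEATURES",
]

#: Default 11-feature panel: clinical, glymphatic and genetic baseline data.
DEFAULT_FEATURES = (
    "updrs1",
    "updrs2",
    "updrs3",
    "moca",
    "gds",
    "stai",
    "rbdsq",
    "scopa_aut",
    "alps_mean",
    "risk_dosage",
    "age",
)


@dataclass(frozen=True)
class VAEConfig:
    """Architecture and training hyperparameters.

    The final encoder layer has ``2 * latent_dim`` units: per latent
    component one mean and one log-variance.
    """

    input_dim: int = 11
    hidden_dim: int = 16
    latent_dim: int = 2
    epochs: int = 1000
    batch_size: int = 40
    learning_rate: float = 0.001
    seed: int = 0

    @property
    def encoder_out(self) -> int:
        return 2 * self.latent_dim

    def architecture(self) -> dict:
        """Dump of the layer structure, for reproducibility records."""
        return {
            "encoder": [self.input_dim, self.hidden_dim, self.encoder_out],
            "encoder_activation": "relu",
            "latent_dim": self.latent_dim,
            "decoder": [self.latent_dim, self.hidden_dim, self.input_dim],
            "decoder_output": "linear",
            "loss": "elbo",
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
        }


def build_feature_table(
    visits: pd.DataFrame,
    labels: pd.DataFrame | None = None,
    alps: pd.DataFrame | None = None,
    genotypes: pd.DataFrame | None = None,
    risk_snps: list[str] | None = None,
    features: tuple[str, ...] = DEFAULT_FEATURES,
) -> pd.DataFrame:
    """Assemble and z-score the baseline feature matrix.

    Takes each subject's baseline (earliest) visit, merges the
    bilateral-mean ALPS index and the summed dosage over risk SNPs, and
    standardizes every column. Subjects with any missing feature are
    dropped (flagged via the returned frame's attrs); zero-variance
    columns raise an error at standardization. Requires at least 11
    available features.
    """
    base = visits.sort_values("time_years").groupby("subject_id").first().reset_index()
    df = base.copy()
    if alps is not None:
        mean_alps = alps.groupby("subject_id")["alps_index"].mean().rename("alps_mean")
        df = df.merge(mean_alps, on="subject_id", how="left")
    if genotypes is not None:
        snps = risk_snps if risk_snps is not None else list(genotypes.columns)
        dosage = genotypes[snps].sum(axis=1, skipna=True).rename("risk_dosage")
        df = df.merge(dosage, left_on="subject_id", right_index=True, how="left")
    missing_cols = [f for f in features if f not in df.columns]
    if len(features) - len(missing_cols) < 11:
        raise ValueError(f"fewer than 11 features available; missing {missing_cols}")
    X = df.set_index("subject_id")[list(features)]
    n_before = len(X)
    X = X.dropna()
    sd = X.std(ddof=0)
    if (sd == 0).any():
        zero = list(sd.index[sd == 0])
        raise ValueError(f"zero-variance feature column(s): {zero}")
    Z = (X - X.mean()) / sd
    Z.attrs["n_dropped_missing"] = n_before - len(X)
    if labels is not None:
        lab = labels.drop_duplicates("subject_id").set_index("subject_id")
        Z.attrs["labels"] = lab
    return Z


@dataclass
class VAEModel:
    config: VAEConfig
    params: dict = field(default_factory=dict)
    curve: pd.DataFrame | None = None


def _init_params(cfg: VAEConfig, rng: np.random.Generator) -> dict:
    def glorot(n_in, n_out):
        s = np.sqrt(2.0 / (n_in + n_out))
        return rng.normal(0, s, (n_in, n_out))

    return {
        "W1": glorot(cfg.input_dim, cfg.hidden_dim),
        "b1": np.zeros(cfg.hidden_dim),
        "W2": glorot(cfg.hidden_dim, cfg.encoder_out),
        "b2": np.zeros(cfg.encoder_out),
        "W3": glorot(cfg.latent_dim, cfg.hidden_dim),
        "b3": np.zeros(cfg.hidden_dim),
        "W4": glorot(cfg.hidden_dim, cfg.input_dim),
        "b4": np.zeros(cfg.input_dim),
    }


def _forward_backward(X: np.ndarray, p: dict, eps: np.ndarray):
    """One minibatch pass; returns (loss, recon, kl, grads)."""
    B = X.shape[0]
    k = eps.shape[1]
    H1 = X @ p["W1"] + p["b1"]
    A1 = np.maximum(H1, 0)
    E = A1 @ p["W2"] + p["b2"]
    mu, lv = E[:, :k], E[:, k:]
    lv = np.clip(lv, -15, 15)
    z = mu + np.exp(0.5 * lv) * eps
    H2 = z @ p["W3"] + p["b3"]
    A2 = np.maximum(H2, 0)
    Xh = A2 @ p["W4"] + p["b4"]

    recon = 0.5 * np.sum((X - Xh) ** 2) / B
    kl = 0.5 * np.sum(mu**2 + np.exp(lv) - 1.0 - lv) / B
    loss = recon + kl

    dXh = (Xh - X) / B
    g = {}
    g["W4"] = A2.T @ dXh
    g["b4"] = dXh.sum(axis=0)
    dA2 = dXh @ p["W4"].T
    dH2 = dA2 * (H2 > 0)
    g["W3"] = z.T @ dH2
    g["b3"] = dH2.sum(axis=0)
    dz = dH2 @ p["W3"].T
    dmu = dz + mu / B
    dlv = dz * eps * 0.5 * np.exp(0.5 * lv) + 0.5 * (np.exp(lv) - 1.0) / B
    dE = np.concatenate([dmu, dlv], axis=1)
    g["W2"] = A1.T @ dE
    g["b2"] = dE.sum(axis=0)
    dA1 = dE @ p["W2"].T
    dH1 = dA1 * (H1 > 0)
    g["W1"] = X.T @ dH1
    g["b1"] = dH1.sum(axis=0)
    return loss, recon, kl, g


def train_vae(features, config: VAEConfig | None = None) -> VAEModel:
    """Train the VAE on a standardized feature matrix.

    ``features`` is an (n, input_dim) array or DataFrame with
    n >= batch_size. Returns the trained model with a per-epoch
    training curve (negative ELBO and its reconstruction / KL parts).
    Raises if the loss diverges to a non-finite value, reporting the
    epoch.
    """
    cfg = config or VAEConfig()
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if X.ndim != 2 or X.shape[1] != cfg.input_dim:
        raise ValueError(f"features must be (n, {cfg.input_dim})")
    if n < cfg.batch_size:
        raise ValueError("need at least one full batch of subjects")
    rng = np.random.default_rng(cfg.seed)
    p = _init_params(cfg, rng)
    m = {k: np.zeros_like(v) for k, v in p.items()}
    v = {k: np.zeros_like(val) for k, val in p.items()}
    b1, b2, adam_eps = 0.9, 0.999, 1e-8
    t = 0
    curve = []
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        ep_loss = ep_recon = ep_kl = 0.0
        n_batches = 0
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            eps = rng.standard_normal((len(idx), cfg.latent_dim))
            loss, recon, kl, grads = _forward_backward(X[idx], p, eps)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            t += 1
            for key in p:
                m[key] = b1 * m[key] + (1 - b1) * grads[key]
                v[key] = b2 * v[key] + (1 - b2) * grads[key] ** 2
                mhat = m[key] / (1 - b1**t)
                vhat = v[key] / (1 - b2**t)
                p[key] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + adam_eps)
            ep_loss += loss
            ep_recon += recon
            ep_kl += kl
            n_batches += 1
        curve.append(
            {
                "epoch": epoch,
                "neg_elbo": ep_loss / n_batches,
                "recon": ep_recon / n_batches,
                "kl": ep_kl / n_batches,
            }
        )
    return VAEModel(config=cfg, params=p, curve=pd.DataFrame(curve))


def embed(model: VAEModel, features) -> np.ndarray:
    """Posterior-mean latent embedding (deterministic, no sampling)."""
    X = np.asarray(features, dtype=float)
    p = model.params
    A1 = np.maximum(X @ p["W1"] + p["b1"], 0)
    E = A1 @ p["W2"] + p["b2"]
    return E[:, : model.config.latent_dim]


def reconstruct(model: VAEModel, features) -> np.ndarray:
    """Decoder output at the posterior mean."""
    z = embed(model, features)
    p = model.params
    A2 = np.maximum(z @ p["W3"] + p["b3"], 0)
    return A2 @ p["W4"] + p["b4"]


def embed_and_compare(model: VAEModel, features: pd.DataFrame, labels: pd.Series):
    """Embed subjects and test group separation per latent component.

    ``labels`` indexes subjects to a binary contrast (e.g. body-first vs
    brain-first). Returns ``(embedding_frame, tests_frame)`` where tests
    hold a Student's t statistic and p-value per latent component.
    Raises when a group has fewer than 2 subjects.
    """
    Z = embed(model, features)
    emb = pd.DataFrame(
        Z,
        index=features.index if hasattr(features, "index") else None,
        columns=[f"component_{i+1}" for i in range(Z.shape[1])],
    )
    lab = labels.reindex(emb.index) if hasattr(features, "index") else pd.Series(labels)
    groups = lab.dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"need a binary contrast, got {list(groups)}")
    a_mask = (lab == groups[0]).to_numpy()
    b_mask = (lab == groups[1]).to_numpy()
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    tests = []
    for i, comp in enumerate(emb.columns):
        t, pval = scipy.stats.ttest_ind(Z[a_mask, i], Z[b_mask, i])
        tests.append({"component": comp, "t": float(t), "p": float(pval),
                      "group_a": groups[0], "group_b": groups[1]})
    emb["label"] = lab.to_numpy() if hasattr(features, "index") else lab.values
    return emb, pd.DataFrame(tests)


def config_dump(cfg: VAEConfig) -> dict:
    """Full configuration echo (architecture + training settings)."""
    d = asdict(cfg)
    d.update(cfg.architecture())
    return d
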