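"""Pathway-mask-guided multi-omics variational autoencoder.

The encoder maps gene expression to a pathway layer through a sparse,
mask-constrained affine map (a weight exists only where the gene belongs to
the pathway), concatenates the pathway activations with the miRNA layer
(optionally passed through its own hidden layer), and forward-propagates to
the means mu and log-variances log sigma^2 of a Gaussian posterior over the
latent variables z.  The decoder reconstructs both omics blocks from a sample
z_hat = mu + sigma * eps; the final map of the gene head is constrained by the
transposed pathway mask, and sigmoid outputs keep reconstructions in (0, 1).

Loss (per batch):  BCE(x_gene, x^_gene) + BCE(x_mirna, x^_mirna)
                   + beta * KL(N(mu, sigma^2) || N(0, I)) + lambda1 * ||theta||^2

with BCE summed over features and averaged over the batch (so the meaning of
beta does not depend on batch size), and the KL term in closed form,
0.5 * sum_d (mu_d^2 + sigma_d^2 - log sigma_d^2 - 1), averaged over the batch.
Batch normalization is applied to all layers except the latent bottleneck;
hidden layers use ReLU, the bottleneck heads are linear.

Single-omics variants: ``gene_only`` drops the miRNA branch and head;
``mirna_only`` drops the gene/pathway side entirely (no mask).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from ._nn import (
    Adam,
    BatchNorm1d,
    Dense,
    ReLU,
    Sequential,
    add_l2_gradients,
    l2_penalty,
    sigmoid,
    softplus,
)
from .pathways import PathwayMask

__all__ = ["VAEConfig", "LatentRepresentation", "KLPMVAE", "vae_loss", "reparameterize"]

_EPS = 1e-7


@dataclass
class VAEConfig:
    n_latent: int = 16
    integration_mode: str = "entangle"  # entangle | gene_only | mirna_only
    lambda1: float = 1e-4
    mirna_hidden: int | None = None  # None = concatenate the miRNA layer directly
    trunk_hidden: int = 256
    batchnorm: bool = True
    learning_rate: float = 1e-3
    epochs: int = 150
    batch_size: int = 128

    def __post_init__(self):
        if self.n_latent < 1:
            raise ValueError("n_latent must be >= 1")
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be >= 0")
        if self.integration_mode not in ("entangle", "gene_only", "mirna_only"):
            raise ValueError(f"unknown integration_mode {self.integration_mode!r}")


@dataclass
class LatentRepresentation:
    """Per-sample posterior means and log-variances."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.logvar = np.asarray(self.logvar, dtype=float)
        if self.mu.shape != self.logvar.shape:
            raise ValueError("mu and logvar must have the same shape")
        if not (np.isfinite(self.mu).all() and np.isfinite(self.logvar).all()):
            raise ValueError("latent representation must be finite")

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(0.5 * self.logvar)


def reparameterize(latent: LatentRepresentation, rng: np.random.Generator) -> np.ndarray:
    """z_hat = mu + sigma * eps with eps ~ N(0, I)."""
    eps = rng.standard_normal(latent.mu.shape)
    return latent.mu + latent.sigma * eps


def gaussian_kl(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Mean over samples of KL(N(mu, sigma^2) || N(0, I)), closed form."""
    per_sample = 0.5 * np.sum(mu**2 + np.exp(logvar) - logvar - 1.0, axis=1)
    return float(per_sample.mean())


def _bce(x: np.ndarray, xhat: np.ndarray) -> float:
    """Binary cross-entropy, summed over features, averaged over samples."""
    if np.any(xhat < 0) or np.any(xhat > 1):
        raise ValueError("reconstructions must lie in [0, 1] for BCE")
    if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
        raise ValueError("BCE targets must lie in [0, 1]")
    y = np.clip(xhat, _EPS, 1.0 - _EPS)
    ll = x * np.log(y) + (1.0 - x) * np.log(1.0 - y)
    return float(-ll.sum(axis=1).mean())


def vae_loss(
    x_gene,
    x_mirna,
    xhat_gene,
    xhat_mirna,
    latent: LatentRepresentation,
    beta: float,
    lambda1: float = 0.0,
    params=None,
) -> tuple[float, dict[str, float]]:
    """Total VAE objective with per-component values for logging.

    Either omics block may be None (single-omics variants).
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    comps = {"recon_gene": 0.0, "recon_mirna": 0.0}
    if x_gene is not None:
        comps["recon_gene"] = _bce(np.asarray(x_gene, float), np.asarray(xhat_gene, float))
    if x_mirna is not None:
        comps["recon_mirna"] = _bce(np.asarray(x_mirna, float), np.asarray(xhat_mirna, float))
    comps["kl"] = gaussian_kl(latent.mu, latent.logvar)
    comps["l2"] = l2_penalty(params, lambda1) if params is not None else 0.0
    total = comps["recon_gene"] + comps["recon_mirna"] + beta * comps["kl"] + comps["l2"]
    return float(total), comps


class KLPMVAE:
    """The pathway-masked VAE with manual backprop (see module docstring)."""

    def __init__(
        self,
        mask: PathwayMask | None,
        n_mirnas: int | None,
        config: VAEConfig | None = None,
        seed: int = 0,
    ):
        self.config = cfg = config or VAEConfig()
        self.mask = mask
        self.n_mirnas = n_mirnas
        mode = cfg.integration_mode
        if mode in ("entangle", "gene_only") and mask is None:
            raise ValueError(f"integration_mode {mode!r} requires a pathway mask")
        if mode in ("entangle", "mirna_only") and not n_mirnas:
            raise ValueError(f"integration_mode {mode!r} requires n_mirnas")
        rng = np.random.default_rng(seed)
        H, d = cfg.trunk_hidden, cfg.n_latent
        bn = cfg.batchnorm

        def _stack(*layers):
            return Sequential(*[l for l in layers if l is not None])

        P = mask.n_pathways if mask is not None else 0
        self.gene_stack = None
        self.mirna_stack = None
        if mode in ("entangle", "gene_only"):
            self.gene_stack = _stack(
                Dense(mask.n_genes, P, rng, mask=mask.mask, name="enc_gene"),
                BatchNorm1d(P, name="enc_gene_bn") if bn else None,
                ReLU(),
            )
        mirna_dim = 0
        if mode in ("entangle", "mirna_only"):
            if cfg.mirna_hidden:
                self.mirna_stack = _stack(
                    Dense(n_mirnas, cfg.mirna_hidden, rng, name="enc_mirna"),
                    BatchNorm1d(cfg.mirna_hidden, name="enc_mirna_bn") if bn else None,
                    ReLU(),
                )
                mirna_dim = cfg.mirna_hidden
            else:
                mirna_dim = n_mirnas
        self._concat_dim = (P if self.gene_stack else 0) + mirna_dim

        self.trunk = _stack(
            Dense(self._concat_dim, H, rng, name="enc_trunk"),
            BatchNorm1d(H, name="enc_trunk_bn") if bn else None,
            ReLU(),
        )
        self.head_mu = Dense(H, d, rng, name="head_mu")
        self.head_logvar = Dense(H, d, rng, name="head_logvar")

        self.dec_trunk = _stack(
            Dense(d, H, rng, name="dec_trunk"),
            BatchNorm1d(H, name="dec_trunk_bn") if bn else None,
            ReLU(),
        )
        self.dec_gene = None
        self.dec_mirna = None
        if mode in ("entangle", "gene_only"):
            # logits; sigmoid applied at the output
            self.dec_gene = _stack(
                Dense(H, P, rng, name="dec_gene_hidden"),
                BatchNorm1d(P, name="dec_gene_bn") if bn else None,
                ReLU(),
                Dense(P, mask.n_genes, rng, mask=mask.mask.T, name="dec_gene_out"),
            )
        if mode in ("entangle", "mirna_only"):
            self.dec_mirna = Dense(H, n_mirnas, rng, name="dec_mirna_out")

    # -- plumbing -----------------------------------------------------------
    @property
    def mode(self) -> str:
        return self.config.integration_mode

    def _stacks(self):
        out = {"trunk": self.trunk, "head_mu": self.head_mu,
               "head_logvar": self.head_logvar, "dec_trunk": self.dec_trunk}
        if self.gene_stack is not None:
            out["gene_stack"] = self.gene_stack
        if self.mirna_stack is not None:
            out["mirna_stack"] = self.mirna_stack
        if self.dec_gene is not None:
            out["dec_gene"] = self.dec_gene
        if self.dec_mirna is not None:
            out["dec_mirna"] = self.dec_mirna
        return out

    def params(self):
        params = []
        for stack in self._stacks().values():
            params.extend(stack.params())
        return params

    def _validate(self, x_gene, x_mirna):
        """Align inputs with the mask/miRNA orderings; returns float arrays."""
        xg = xm = None
        if self.gene_stack is not None:
            if x_gene is None:
                raise ValueError("this model requires gene expression input")
            if isinstance(x_gene, pd.DataFrame):
                if list(x_gene.columns) != self.mask.gene_ids:
                    bad = [c for c, g in zip(x_gene.columns, self.mask.gene_ids) if c != g]
                    raise ValueError(
                        f"gene features misaligned with pathway mask; first mismatches: {bad[:5]}"
                    )
                x_gene = x_gene.to_numpy()
            xg = np.asarray(x_gene, dtype=float)
            if xg.shape[1] != self.mask.n_genes:
                raise ValueError(f"expected {self.mask.n_genes} genes, got {xg.shape[1]}")
        if self.mode in ("entangle", "mirna_only"):
            if x_mirna is None:
                raise ValueError("this model requires miRNA expression input")
            if isinstance(x_mirna, pd.DataFrame):
                x_mirna = x_mirna.to_numpy()
            xm = np.asarray(x_mirna, dtype=float)
            if xm.shape[1] != self.n_mirnas:
                raise ValueError(f"expected {self.n_mirnas} miRNAs, got {xm.shape[1]}")
        return xg, xm

    # -- forward ------------------------------------------------------------
    def encode(self, x_gene, x_mirna=None, training: bool = False) -> LatentRepresentation:
        xg, xm = self._validate(x_gene, x_mirna)
        parts = []
        if self.gene_stack is not None:
            parts.append(self.gene_stack.forward(xg, training=training))
        if xm is not None:
            parts.append(
                self.mirna_stack.forward(xm, training=training)
                if self.mirna_stack is not None
                else xm
            )
        c = np.concatenate(parts, axis=1)
        t = self.trunk.forward(c, training=training)
        mu = self.head_mu.forward(t, training=training)
        logvar = self.head_logvar.forward(t, training=training)
        return LatentRepresentation(mu=mu, logvar=logvar)

    def decode(self, z, training: bool = False):
        """Reconstructions in (0, 1); returns (x^_gene, x^_mirna), either may be None."""
        z = np.asarray(z, dtype=float)
        t = self.dec_trunk.forward(z, training=training)
        xg = sigmoid(self.dec_gene.forward(t, training=training)) if self.dec_gene else None
        xm = sigmoid(self.dec_mirna.forward(t, training=training)) if self.dec_mirna else None
        if self.mode == "gene_only":
            return xg
        if self.mode == "mirna_only":
            return xm
        return xg, xm

    def extract_latent(self, x_gene, x_mirna=None) -> np.ndarray:
        """Deterministic posterior means mu in evaluation state (no sampling)."""
        return self.encode(x_gene, x_mirna, training=False).mu

    # -- training -----------------------------------------------------------
    def _train_step(self, xg, xm, beta: float, rng: np.random.Generator):
        """One forward/backward pass; returns loss components."""
        cfg = self.config
        B = (xg if xg is not None else xm).shape[0]

        parts, widths = [], []
        if self.gene_stack is not None:
            pa = self.gene_stack.forward(xg, training=True)
            parts.append(pa)
            widths.append(pa.shape[1])
        if xm is not None:
            mb = (self.mirna_stack.forward(xm, training=True)
                  if self.mirna_stack is not None else xm)
            parts.append(mb)
            widths.append(mb.shape[1])
        c = np.concatenate(parts, axis=1)
        t = self.trunk.forward(c, training=True)
        mu = self.head_mu.forward(t, training=True)
        logvar = self.head_logvar.forward(t, training=True)
        sig = np.exp(0.5 * np.clip(logvar, -30.0, 30.0))
        eps = rng.standard_normal(mu.shape)
        z = mu + sig * eps

        td = self.dec_trunk.forward(z, training=True)
        comps = {"recon_gene": 0.0, "recon_mirna": 0.0}
        dtd = np.zeros_like(td)
        if self.dec_gene is not None:
            glog = self.dec_gene.forward(td, training=True)
            # stable BCE from logits: softplus(a) - x*a
            comps["recon_gene"] = float((softplus(glog) - xg * glog).sum(1).mean())
            dtd += self.dec_gene.backward((sigmoid(glog) - xg) / B)
        if self.dec_mirna is not None:
            mlog = self.dec_mirna.forward(td, training=True)
            comps["recon_mirna"] = float((softplus(mlog) - xm * mlog).sum(1).mean())
            dtd += self.dec_mirna.backward((sigmoid(mlog) - xm) / B)
        comps["kl"] = gaussian_kl(mu, logvar)

        dz = self.dec_trunk.backward(dtd)
        dmu = dz + beta * mu / B
        dlogvar = dz * eps * 0.5 * sig + beta * 0.5 * (np.exp(logvar) - 1.0) / B
        dt = self.head_mu.backward(dmu) + self.head_logvar.backward(dlogvar)
        dc = self.trunk.backward(dt)
        offset = 0
        chunks = []
        for w in widths:
            chunks.append(dc[:, offset:offset + w])
            offset += w
        i = 0
        if self.gene_stack is not None:
            self.gene_stack.backward(chunks[i]); i += 1
        if xm is not None and self.mirna_stack is not None:
            self.mirna_stack.backward(chunks[i])

        params = self.params()
        add_l2_gradients(params, cfg.lambda1)
        comps["l2"] = l2_penalty(params, cfg.lambda1)
        comps["loss"] = (comps["recon_gene"] + comps["recon_mirna"]
                         + beta * comps["kl"] + comps["l2"])
        return comps

    def reconstruction_loss(self, x_gene, x_mirna=None) -> float:
        """Eval-mode total BCE reconstruction loss (no KL, no penalty)."""
        xg, xm = self._validate(x_gene, x_mirna)
        latent = self.encode(x_gene, x_mirna, training=False)
        out = self.decode(latent.mu, training=False)  # deterministic: decode at mu
        if self.mode == "gene_only":
            return _bce(xg, out)
        if self.mode == "mirna_only":
            return _bce(xm, out)
        return _bce(xg, out[0]) + _bce(xm, out[1])

    def fit(
        self,
        x_gene,
        x_mirna=None,
        beta_schedule=None,
        seed: int = 0,
        validation=None,
        verbose: bool = False,
    ) -> pd.DataFrame:
        """Train with Adam and a per-epoch KL-annealing schedule.

        ``beta_schedule`` may be None (constant beta = 1), a callable
        ``epoch -> beta``, or a training.AnnealingSchedule whose total_steps
        must equal the number of epochs.
        """
        cfg = self.config
        xg, xm = self._validate(x_gene, x_mirna)
        n = (xg if xg is not None else xm).shape[0]
        rng = np.random.default_rng(seed)
        params = self.params()
        opt = Adam(params, lr=cfg.learning_rate)

        if beta_schedule is None:
            beta_fn = lambda e: 1.0
        elif callable(beta_schedule):
            beta_fn = beta_schedule
        else:
            from .train import beta_at
            beta_fn = lambda e: beta_at(e, beta_schedule)

        history = []
        for epoch in range(cfg.epochs):
            beta = float(beta_fn(epoch))
            order = rng.permutation(n)
            totals = {}
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                if len(idx) < 2 and cfg.batchnorm:
                    continue  # batchnorm needs >= 2 samples
                opt.zero_grad()
                comps = self._train_step(
                    xg[idx] if xg is not None else None,
                    xm[idx] if xm is not None else None,
                    beta, rng,
                )
                opt.step()
                n_batches += 1
                for key, val in comps.items():
                    totals[key] = totals.get(key, 0.0) + val
            record = {"epoch": epoch, "beta": beta}
            record.update({k: v / max(n_batches, 1) for k, v in totals.items()})
            if validation is not None:
                record["valid_recon"] = self.reconstruction_loss(*validation)
            history.append(record)
            if verbose and epoch % 20 == 0:
                print(f"epoch {epoch}: loss {record['loss']:.3f} beta {beta:.2f}")
        return pd.DataFrame(history)

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        arrays = {p.name: p.value for p in self.params()}
        for sname, stack in self._stacks().items():
            layers = stack.layers if isinstance(stack, Sequential) else [stack]
            for i, layer in enumerate(layers):
                if isinstance(layer, BatchNorm1d):
                    arrays[f"__rs__{sname}.{i}.mean"] = layer.running_mean
                    arrays[f"__rs__{sname}.{i}.var"] = layer.running_var
        meta = {
            "config": asdict(self.config),
            "n_mirnas": self.n_mirnas,
            "mask": None if self.mask is None else {
                "gene_ids": self.mask.gene_ids,
                "pathway_ids": self.mask.pathway_ids,
            },
        }
        mask_arr = {} if self.mask is None else {"__mask__": self.mask.mask}
        np.savez(path, __meta__=np.array([repr(meta)], dtype=object), **mask_arr, **arrays)

    @classmethod
    def load(cls, path) -> "KLPMVAE":
        data = np.load(path, allow_pickle=True)
        meta = eval(data["__meta__"][0])  # noqa: S307 - our own checkpoint format
        mask = None
        if meta["mask"] is not None:
            mask = PathwayMask(
                gene_ids=meta["mask"]["gene_ids"],
                pathway_ids=meta["mask"]["pathway_ids"],
                mask=data["__mask__"],
            )
        model = cls(mask, meta["n_mirnas"], VAEConfig(**meta["config"]))
        for p in model.params():
            p.value[...] = data[p.name]
        for sname, stack in model._stacks().items():
            layers = stack.layers if isinstance(stack, Sequential) else [stack]
            for i, layer in enumerate(layers):
                if isinstance(layer, BatchNorm1d):
                    layer.running_mean = data[f"__rs__{sname}.{i}.mean"]
                    layer.running_var = data[f"__rs__{sname}.{i}.var"]
        return model
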