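"""DeepSHAP attribution with the DeepLIFT rescale rule, in numpy.

Trained networks are folded into chains of affine maps (batchnorm running
statistics folded into the adjacent dense layer, exact in evaluation state)
and elementwise nonlinearities.  For an explained sample x and a single
reference r, multipliers are backpropagated from the explained output:
through an affine map they propagate as m W^T; through a nonlinearity each
unit's multiplier is scaled by (f(a_x) - f(a_r)) / (a_x - a_r) (the rescale
rule), falling back to f'(a_x) when the pre-activation difference vanishes.
The contribution of input k is then m_k * (x_k - r_k), which satisfies
summation-to-delta: contributions sum exactly to f(x) - f(r).

DeepSHAP averages these DeepLIFT contributions over a reference cohort (here
the predicted low-risk group); the overall contribution score of a feature is
the mean of its absolute averaged contributions over the explained (high-risk)
samples, and percent contributions normalize the overall scores to 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import BatchNorm1d, Dense, Dropout, ReLU, Sequential, Sigmoid, Tanh, sigmoid

__all__ = [
    "AttributionResult",
    "KeyFactorReport",
    "deep_shap",
    "explain_pi",
    "explain_latent",
    "explain_pathway_node",
    "overall_contributions",
    "percent_contributions",
    "identify_key_factors",
]

_RESCALE_EPS = 1e-7

_ACTS = {
    "relu": (lambda a: np.maximum(a, 0.0), lambda a: (a > 0).astype(float)),
    "tanh": (np.tanh, lambda a: 1.0 - np.tanh(a) ** 2),
    "sigmoid": (sigmoid, lambda a: sigmoid(a) * (1.0 - sigmoid(a))),
}


# ---------------------------------------------------------------------------
# chains: [("affine", W, b) | ("act", kind)]

def fold_stack(stack) -> list[tuple]:
    """Fold a Sequential (or single Dense) into an affine/nonlinearity chain."""
    layers = stack.layers if isinstance(stack, Sequential) else [stack]
    ops: list[tuple] = []
    for layer in layers:
        if isinstance(layer, Dense):
            b = layer.b.value.copy() if layer.b is not None else np.zeros(layer.W.value.shape[1])
            ops.append(("affine", layer.W.value.copy(), b))
        elif isinstance(layer, BatchNorm1d):
            scale, shift = layer.folded()
            if ops and ops[-1][0] == "affine":
                _, W, b = ops[-1]
                ops[-1] = ("affine", W * scale[None, :], b * scale + shift)
            else:
                ops.append(("affine", np.diag(scale), shift))
        elif isinstance(layer, (ReLU, Tanh, Sigmoid)):
            ops.append(("act", layer.kind))
        elif isinstance(layer, Dropout):
            continue  # identity in evaluation state
        else:
            raise TypeError(f"cannot fold layer {type(layer).__name__}")
    return ops


def select_output(ops: list[tuple], index: int) -> list[tuple]:
    """Append a selector so the chain's output is one scalar coordinate."""
    if ops and ops[-1][0] == "affine":
        _, W, b = ops[-1]
        return ops[:-1] + [("affine", W[:, [index]], b[[index]])]
    width = None
    for kind, *rest in reversed(ops):
        if kind == "affine":
            width = rest[0].shape[1]
            break
    if width is None:
        raise ValueError("chain has no affine op to infer width from")
    sel = np.zeros((width, 1))
    sel[index, 0] = 1.0
    return ops + [("affine", sel, np.zeros(1))]


def chain_forward(ops, x: np.ndarray) -> list[np.ndarray]:
    """All intermediate values; acts[i] is the input of op i, acts[-1] the output."""
    acts = [np.asarray(x, dtype=float)]
    for op in ops:
        if op[0] == "affine":
            acts.append(acts[-1] @ op[1] + op[2])
        else:
            acts.append(_ACTS[op[1]][0](acts[-1]))
    return acts


def chain_multipliers(
    ops, acts_x: list[np.ndarray], acts_r: list[np.ndarray], m0: np.ndarray | None = None
) -> np.ndarray:
    """Backpropagate rescale-rule multipliers from the chain output to its input.

    ``acts_r`` holds activations of a single reference (shape (1, d) per op).
    ``m0`` is the multiplier at the chain output (defaults to ones, for a
    scalar-output chain).
    """
    m = np.ones((acts_x[-1].shape[0], acts_x[-1].shape[1])) if m0 is None else m0
    for i in range(len(ops) - 1, -1, -1):
        op = ops[i]
        if op[0] == "affine":
            m = m @ op[1].T
        else:
            f, fprime = _ACTS[op[1]]
            ax, ar = acts_x[i], acts_r[i]
            din = ax - ar
            dout = f(ax) - f(ar)
            with np.errstate(divide="ignore", invalid="ignore"):
                scale = np.where(np.abs(din) > _RESCALE_EPS, dout / din, fprime(ax))
            m = m * scale
    return m


# ---------------------------------------------------------------------------
# results

@dataclass
class AttributionResult:
    """Reference-averaged per-sample contributions toward one explained output."""

    target: str
    feature_ids: list[str]
    contributions: np.ndarray       # (n_explained, n_features)
    output_values: np.ndarray       # explained outputs, (n_explained,)
    reference_mean_output: float
    explained_ids: list[str]
    reference_ids: list[str]
    seed: int | None = None

    @property
    def overall(self) -> pd.Series:
        """Mean absolute contribution over explained samples, per feature."""
        return pd.Series(
            np.abs(self.contributions).mean(axis=0), index=self.feature_ids,
            name="overall_contribution",
        )

    def summation_to_delta_error(self) -> float:
        """Max relative deviation of sum(contributions) from Delta(output)."""
        delta = self.output_values - self.reference_mean_output
        err = np.abs(self.contributions.sum(axis=1) - delta)
        return float(np.max(err / (1.0 + np.abs(delta))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.contributions, index=self.explained_ids, columns=self.feature_ids
        )


def overall_contributions(attr: AttributionResult) -> pd.Series:
    """Per-feature overall score: mean |contribution| over explained samples."""
    return attr.overall


def percent_contributions(overall: pd.Series) -> pd.Series:
    """Percent contributions: overall / sum(overall) * 100."""
    total = float(np.sum(overall))
    if total <= 0:
        raise ValueError("total overall contribution is zero; cannot normalize")
    return (overall / total * 100.0).rename("percent_contribution")


def subsample_ids(ids, max_n: int, rng: np.random.Generator) -> list:
    """Seeded sample of up to max_n ids without replacement (all if fewer)."""
    ids = list(ids)
    if len(ids) <= max_n:
        return ids
    return [ids[i] for i in sorted(rng.choice(len(ids), size=max_n, replace=False))]


def _as_array(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.index.astype(str))
    X = np.asarray(X, dtype=float)
    return X, [str(i) for i in range(X.shape[0])]


def deep_shap(
    chain: list[tuple],
    explained,
    reference,
    feature_ids,
    target: str = "output",
    seed: int | None = None,
    max_samples: int = 100,
) -> AttributionResult:
    """Rescale-rule DeepSHAP over a folded scalar-output chain.

    Contributions are computed against each reference sample separately and
    averaged (the Shapley-style reading of DeepSHAP); when explained or
    reference cohorts exceed ``max_samples``, a seeded subsample is used.
    """
    Xe, e_ids = _as_array(explained)
    Xr, r_ids = _as_array(reference)
    if Xr.shape[0] == 0:
        raise ValueError("reference set is empty")
    rng = np.random.default_rng(seed)
    keep_e = subsample_ids(range(Xe.shape[0]), max_samples, rng)
    keep_r = subsample_ids(range(Xr.shape[0]), max_samples, rng)
    Xe, e_ids = Xe[keep_e], [e_ids[i] for i in keep_e]
    Xr, r_ids = Xr[keep_r], [r_ids[i] for i in keep_r]

    acts_x = chain_forward(chain, Xe)
    out_x = acts_x[-1][:, 0]
    total = np.zeros_like(Xe)
    ref_outputs = []
    for r in Xr:
        acts_r = chain_forward(chain, r[None, :])
        ref_outputs.append(acts_r[-1][0, 0])
        m = chain_multipliers(chain, acts_x, acts_r)
        total += m * (Xe - r[None, :])
    contributions = total / Xr.shape[0]
    return AttributionResult(
        target=target,
        feature_ids=list(feature_ids),
        contributions=contributions,
        output_values=out_x,
        reference_mean_output=float(np.mean(ref_outputs)),
        explained_ids=e_ids,
        reference_ids=r_ids,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# model-specific explainers

def explain_pi(model, explained, reference, seed: int | None = None,
               max_samples: int = 100) -> AttributionResult:
    """Contributions of survival-network inputs (latent features + clinical
    covariates) to the prognostic index."""
    chain = fold_stack(model.net)
    if isinstance(explained, pd.DataFrame):
        feature_ids = list(explained.columns)
    elif model.feature_names is not None:
        feature_ids = model.feature_names
    else:
        feature_ids = [f"x{i}" for i in range(model.n_features)]
    return deep_shap(chain, explained, reference, feature_ids, target="PI",
                     seed=seed, max_samples=max_samples)


def _encoder_parts(vae):
    """Folded branch chains and trunk chain of the VAE encoder."""
    gene_chain = fold_stack(vae.gene_stack) if vae.gene_stack is not None else None
    mirna_chain = fold_stack(vae.mirna_stack) if vae.mirna_stack is not None else None
    trunk_chain = fold_stack(vae.trunk) + fold_stack(vae.head_mu)
    return gene_chain, mirna_chain, trunk_chain


def explain_latent(
    vae,
    latent_index: int,
    explained_gene=None,
    explained_mirna=None,
    reference_gene=None,
    reference_mirna=None,
    level: str = "inputs",
    seed: int | None = None,
    max_samples: int = 100,
) -> AttributionResult:
    """Contributions to one latent-feature mean mu_l.

    ``level='inputs'`` attributes to gene and miRNA inputs; ``level='pathways'``
    attributes to the pathway-layer nodes (plus miRNA features), treating the
    concatenated pathway/miRNA layer as the input layer.
    """
    gene_chain, mirna_chain, trunk_chain = _encoder_parts(vae)
    trunk_chain = select_output(trunk_chain, latent_index)
    mode = vae.mode

    Xg = Rg = Xm = Rm = None
    e_ids = r_ids = None
    if mode in ("entangle", "gene_only"):
        Xg, e_ids = _as_array(explained_gene)
        Rg, r_ids = _as_array(reference_gene)
    if mode in ("entangle", "mirna_only"):
        Xm, ids = _as_array(explained_mirna)
        Rm, rids = _as_array(reference_mirna)
        e_ids, r_ids = e_ids or ids, r_ids or rids

    rng = np.random.default_rng(seed)
    n_e = (Xg if Xg is not None else Xm).shape[0]
    n_r = (Rg if Rg is not None else Rm).shape[0]
    if n_r == 0:
        raise ValueError("reference set is empty")
    keep_e = subsample_ids(range(n_e), max_samples, rng)
    keep_r = subsample_ids(range(n_r), max_samples, rng)
    e_ids = [e_ids[i] for i in keep_e]
    r_ids = [r_ids[i] for i in keep_r]
    if Xg is not None:
        Xg, Rg = Xg[keep_e], Rg[keep_r]
    if Xm is not None:
        Xm, Rm = Xm[keep_e], Rm[keep_r]

    # branch outputs feeding the concat layer
    def branch_out(chain, X):
        return chain_forward(chain, X) if chain is not None else [X]

    acts_gx = branch_out(gene_chain, Xg) if Xg is not None else None
    acts_mx = branch_out(mirna_chain, Xm) if Xm is not None else None
    parts_x = ([acts_gx[-1]] if acts_gx is not None else []) + (
        [acts_mx[-1]] if acts_mx is not None else [])
    Cx = np.concatenate(parts_x, axis=1)
    acts_tx = chain_forward(trunk_chain, Cx)
    out_x = acts_tx[-1][:, 0]

    n_gene_cols = acts_gx[-1].shape[1] if acts_gx is not None else 0
    if isinstance(explained_mirna, pd.DataFrame):
        mirna_ids = list(explained_mirna.columns)
    else:
        mirna_ids = [f"miRNA_{i}" for i in range(vae.n_mirnas or 0)]
    if level == "inputs":
        feature_ids = (list(vae.mask.gene_ids) if Xg is not None else []) + (
            mirna_ids if Xm is not None else [])
        total_g = np.zeros_like(Xg) if Xg is not None else None
        total_m = np.zeros_like(Xm) if Xm is not None else None
    elif level == "pathways":
        feature_ids = (list(vae.mask.pathway_ids) if Xg is not None else []) + (
            mirna_ids if Xm is not None else [])
        total_c = np.zeros_like(Cx)
    else:
        raise ValueError(f"unknown level {level!r}")

    ref_outputs = []
    for ri in range(len(r_ids)):
        rg = Rg[ri][None, :] if Rg is not None else None
        rm = Rm[ri][None, :] if Rm is not None else None
        acts_gr = branch_out(gene_chain, rg) if rg is not None else None
        acts_mr = branch_out(mirna_chain, rm) if rm is not None else None
        parts_r = ([acts_gr[-1]] if acts_gr is not None else []) + (
            [acts_mr[-1]] if acts_mr is not None else [])
        Cr = np.concatenate(parts_r, axis=1)
        acts_tr = chain_forward(trunk_chain, Cr)
        ref_outputs.append(acts_tr[-1][0, 0])
        m_c = chain_multipliers(trunk_chain, acts_tx, acts_tr)
        if level == "pathways":
            total_c += m_c * (Cx - Cr)
            continue
        m_gene_part = m_c[:, :n_gene_cols]
        m_mirna_part = m_c[:, n_gene_cols:]
        if Xg is not None:
            if gene_chain is not None:
                m_g = chain_multipliers(gene_chain, acts_gx, acts_gr, m0=m_gene_part)
            else:
                m_g = m_gene_part
            total_g += m_g * (Xg - rg)
        if Xm is not None:
            if mirna_chain is not None:
                m_m = chain_multipliers(mirna_chain, acts_mx, acts_mr, m0=m_mirna_part)
            else:
                m_m = m_mirna_part
            total_m += m_m * (Xm - rm)

    n_refs = len(r_ids)
    if level == "pathways":
        contributions = total_c / n_refs
    else:
        parts = []
        if total_g is not None:
            parts.append(total_g / n_refs)
        if total_m is not None:
            parts.append(total_m / n_refs)
        contributions = np.concatenate(parts, axis=1)
    return AttributionResult(
        target=f"mu_{latent_index}",
        feature_ids=feature_ids,
        contributions=contributions,
        output_values=out_x,
        reference_mean_output=float(np.mean(ref_outputs)),
        explained_ids=e_ids,
        reference_ids=r_ids,
        seed=seed,
    )


def explain_pathway_node(
    vae, pathway: str, explained_gene, reference_gene,
    seed: int | None = None, max_samples: int = 100,
) -> AttributionResult:
    """Contributions of gene inputs to one pathway-layer node value.

    Only genes connected by the mask can receive nonzero contributions; the
    explained output is the node's post-activation value.
    """
    if vae.gene_stack is None:
        raise ValueError("model has no pathway layer")
    if pathway not in vae.mask.pathway_ids:
        raise ValueError(f"unknown pathway {pathway!r}")
    index = vae.mask.pathway_ids.index(pathway)
    # chain is one (folded) affine followed by the activation; select the
    # pathway's column so the explained output is that node's activation
    chain = fold_stack(vae.gene_stack)
    sel_ops, selected = [], False
    for op in chain:
        if op[0] == "affine" and not selected:
            sel_ops.append(("affine", op[1][:, [index]], op[2][[index]]))
            selected = True
        else:
            sel_ops.append(op)
    res = deep_shap(sel_ops, explained_gene, reference_gene,
                    feature_ids=list(vae.mask.gene_ids),
                    target=f"pathway:{pathway}", seed=seed, max_samples=max_samples)
    return res


# ---------------------------------------------------------------------------
# key factor identification

@dataclass
class KeyFactorReport:
    """Factors ranked in the top-k contributors of multiple latent features."""

    table: pd.DataFrame        # columns: factor, frequency, key
    top_k: int
    min_frequency: int
    examined: list[str]
    ties_flagged: list[str] = field(default_factory=list)

    def key_factors(self) -> list[str]:
        return self.table.loc[self.table["key"], "factor"].tolist()


def _top_k(overall: pd.Series, k: int) -> tuple[list[str], bool]:
    """Top-k feature ids by score, ties broken lexicographically; flags a tie
    spanning the rank-k boundary."""
    order = sorted(overall.index, key=lambda f: (-overall[f], f))
    top = order[:k]
    tie_at_boundary = (
        len(order) > k and overall[order[k - 1]] == overall[order[k]]
    )
    return top, tie_at_boundary


def identify_key_factors(
    per_latent: dict[str, AttributionResult | pd.Series],
    top_k: int = 10,
    min_frequency: int = 2,
) -> KeyFactorReport:
    """Count, per input factor, the examined latent features for which it is a
    top-k contributor; factors reaching ``min_frequency`` are key factors
    (Key Input Factors over gene/miRNA inputs, Key Pathway Factors over
    pathway nodes)."""
    if not per_latent:
        raise ValueError("no latent attributions supplied")
    counts: dict[str, int] = {}
    ties = []
    for name, attr in per_latent.items():
        overall = attr.overall if isinstance(attr, AttributionResult) else attr
        if len(overall) < top_k:
            warnings.warn(
                f"{name}: only {len(overall)} factors available for top-{top_k}",
                stacklevel=2,
            )
        top, tie = _top_k(overall, top_k)
        if tie:
            ties.append(name)
        for f in top:
            counts[f] = counts.get(f, 0) + 1
    table = pd.DataFrame(
        {"factor": list(counts), "frequency": list(counts.values())}
    ).sort_values(["frequency", "factor"], ascending=[False, True], ignore_index=True)
    table["key"] = table["frequency"] >= min_frequency
    return KeyFactorReport(
        table=table, top_k=top_k, min_frequency=min_frequency,
        examined=list(per_latent), ties_flagged=ties,
    )
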