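"""Integrated-gradients attribution of predicted contacts to input genes.

The attribution of gene i to predicted interaction j is

    IG_ij = g_i * integral_0^1 dF_j(alpha * g)/dg_i d(alpha)

from the all-zeros baseline (no expression, stable chromatin), with the
integral approximated by a midpoint Riemann sum.  Per-subtype regulator
scores aggregate the signed IG values over all of a subtype's cells and
all target interactions, then normalize by the maximum absolute score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from contactseer.autodiff import Tensor
from contactseer.model import ContactTransformer

logger = logging.getLogger(__name__)

DEFAULT_STEPS = 50


@dataclass
class AttributionVector:
    """Signed per-gene scores with max-|.|-normalized companion."""

    scores: np.ndarray
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_names) != self.scores.size:
            raise ValueError("gene_names length must match scores")

    @property
    def normalized(self) -> np.ndarray:
        m = np.abs(self.scores).max()
        return self.scores / m if m > 0 else self.scores.copy()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "gene": self.gene_names,
            "score": self.scores,
            "normalized": self.normalized,
        })
        df["rank"] = (-df["normalized"].abs()).rank(method="first").astype(int)
        return df.sort_values("rank").reset_index(drop=True)


def _input_gradient(model: ContactTransformer, x: np.ndarray,
                    target_j: int | None) -> np.ndarray:
    """Gradient of output j (or the sum over all outputs) wrt the input batch."""
    t = Tensor(x, requires_grad=True)
    out = model.forward(t)
    if target_j is None:
        scalar = out.sum()
    else:
        sel = np.zeros(out.shape[1])
        sel[target_j] = 1.0
        scalar = (out * sel).sum()
    scalar.backward()
    return t.grad.reshape(x.shape)


def integrated_gradients(
    model: ContactTransformer,
    g: np.ndarray,
    target_j: int | None,
    steps: int = DEFAULT_STEPS,
) -> np.ndarray:
    """Midpoint-rule integrated gradients from the zero baseline.

    ``target_j`` indexes one predicted interaction; ``None`` attributes the
    sum over all interactions (equivalent to summing per-target IG vectors,
    by linearity of the gradient).  Returns a length-K_R vector aligned with
    the model's full gene axis; truncated genes get attribution 0.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if target_j is not None and not (0 <= target_j < model.n_out):
        raise ValueError(f"target_j={target_j} outside [0, {model.n_out})")
    g = np.asarray(g, dtype=float).ravel()
    x = model.prepare_input(g)  # kept genes only
    alphas = (np.arange(steps) + 0.5) / steps
    grad_sum = np.zeros_like(x)
    chunk = 64  # bound the forward-graph batch size
    for start in range(0, steps, chunk):
        batch = alphas[start:start + chunk, None] * x[None, :]
        grad_sum += _input_gradient(model, batch, target_j).sum(axis=0)
    ig_kept = x * grad_sum / steps
    full = np.zeros(model.spec.K_R)
    full[model.spec.kept_gene_indices] = ig_kept
    return full


def aggregate_attributions(
    model: ContactTransformer,
    inputs: Sequence[np.ndarray],
    targets: Sequence[int] | None = None,
    steps: int = DEFAULT_STEPS,
    aggregate: str = "signed",
) -> AttributionVector:
    """Per-gene regulator score for one cell subtype.

    Sums IG over all cells of the subtype and over the target interactions
    (all of them by default).  ``aggregate="abs"`` sums magnitudes instead
    of signed values.
    """
    if len(inputs) == 0:
        raise ValueError("need at least one input cell")
    if aggregate not in ("signed", "abs"):
        raise ValueError("aggregate must be 'signed' or 'abs'")
    total = np.zeros(model.spec.K_R)
    for g in inputs:
        if targets is None or len(targets) == model.n_out:
            # sum over all interactions collapses to one backward pass per
            # integration step (gradients are linear in the output weights)
            ig = integrated_gradients(model, g, None, steps)
            total += np.abs(ig) if aggregate == "abs" else ig
        else:
            for j in targets:
                ig = integrated_gradients(model, g, j, steps)
                total += np.abs(ig) if aggregate == "abs" else ig
    names = model.gene_names or [f"g{i}" for i in range(model.spec.K_R)]
    return AttributionVector(total, list(names))


def rank_regulators(
    attr: AttributionVector,
    regulator_list: Sequence[str],
    top_fraction: float = 0.1,
) -> pd.DataFrame:
    """Rank regulator genes by |normalized| attribution; flag the top fraction."""
    if len(regulator_list) == 0:
        raise ValueError("regulator list is empty")
    regs = set(regulator_list)
    df = attr.to_frame()
    df["regulator"] = df["gene"].isin(regs)
    sub = df[df["regulator"]].copy()
    if sub.empty:
        logger.warning("no overlap between regulator list and model genes")
        sub["top"] = pd.Series(dtype=bool)
        return sub
    sub = sub.sort_values("rank").reset_index(drop=True)
    n_top = int(np.ceil(top_fraction * len(sub)))
    sub["top"] = np.arange(len(sub)) < n_top
    return sub


def promoter_body_terminator(gene) -> dict:
    """Regions for promoter / gene-body / terminator trainings.

    Promoter and terminator are the gene's start and end positions extended
    by half the gene length on each side; the body is the gene itself.
    """
    from contactseer.io_formats import GenomicFeature

    half = gene.length // 2
    return {
        "promoter": GenomicFeature(f"{gene.name}_promoter", gene.chrom,
                                   max(0, gene.start - half), gene.start + half),
        "body": gene,
        "terminator": GenomicFeature(f"{gene.name}_terminator", gene.chrom,
                                     max(0, gene.end - half), gene.end + half),
    }
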