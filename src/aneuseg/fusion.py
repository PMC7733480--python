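"""Cross-validation folds, STAPLE label fusion, and variant ensembling.

STAPLE (simultaneous truth and performance level estimation) treats each
input mask as a rater with unknown sensitivity ``p_j`` and specificity
``q_j`` and estimates, by expectation-maximization, both the rater
parameters and the per-voxel posterior probability that the latent true
segmentation is foreground. Binary fold outputs of one network variant are
fused this way; the three variant outputs are then combined the same way
(degenerating to a majority vote for symmetric rater qualities) unless the
majority-vote fallback is selected.

The E/M updates are computed exactly on the 2^J distinct rater-vote
patterns rather than per voxel, which makes the EM loop cost independent of
grid size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .volume import Volume3D

__all__ = ["FoldSplit", "StapleResult", "make_folds", "staple", "fuse_folds", "ensemble_combine"]


@dataclass
class FoldSplit:
    """Case-level partition for k-fold cross-validation."""

    k: int
    assignments: dict[str, int]  # case id -> validation fold id

    def fold_cases(self, fold: int) -> list[str]:
        return [c for c, f in self.assignments.items() if f == fold]

    def train_cases(self, fold: int) -> list[str]:
        return [c for c, f in self.assignments.items() if f != fold]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"k": self.k, "assignments": self.assignments}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldSplit":
        d = json.loads(Path(path).read_text())
        return cls(k=d["k"], assignments=d["assignments"])


@dataclass
class StapleResult:
    consensus: Volume3D  # per-voxel posterior of foreground
    per_rater: list[tuple[float, float]]  # (sensitivity p_j, specificity q_j)
    iterations: int
    converged: bool
    degenerate: bool = False
    log_likelihood: list[float] | None = None


def make_folds(case_ids: list[str], seed: int, k: int = 5) -> FoldSplit:
    """Seeded random partition of cases into ``k`` validation folds."""
    if len(case_ids) < k:
        raise ValueError(f"need at least {k} cases for {k}-fold CV, got {len(case_ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(case_ids))
    assignments = {}
    for pos, idx in enumerate(order):
        assignments[case_ids[idx]] = pos % k
    return FoldSplit(k=k, assignments=assignments)


def staple(
    masks: list[Volume3D],
    prior: float | str = "auto",
    tol: float = 1e-6,
    max_iter: int = 100,
    init_pq: float = 0.99,
) -> StapleResult:
    """Binary STAPLE consensus by expectation-maximization.

    ``prior`` is the global foreground probability f; ``"auto"`` uses the
    mean foreground fraction of the inputs. Iterates until the largest
    change in any voxel posterior falls below ``tol`` or ``max_iter``.
    """
    if len(masks) < 2:
        raise ValueError("STAPLE needs at least 2 input masks")
    first = masks[0]
    for m in masks[1:]:
        first.require_same_grid(m, "STAPLE input masks")

    D = np.stack([m.values.astype(bool).ravel() for m in masks])  # (J, V)
    J, V = D.shape

    if not D.any():
        return StapleResult(
            consensus=first.with_values(np.zeros(first.shape, dtype=np.float32)),
            per_rater=[(init_pq, init_pq)] * J,
            iterations=0,
            converged=True,
            degenerate=True,
        )

    f = float(D.mean()) if prior == "auto" else float(prior)
    f = min(max(f, 1e-12), 1 - 1e-12)

    # group voxels by rater-vote pattern: EM cost becomes O(2^J) per step
    codes = np.zeros(V, dtype=np.int64)
    for j in range(J):
        codes |= D[j].astype(np.int64) << j
    patterns, counts = np.unique(codes, return_counts=True)
    votes = ((patterns[:, None] >> np.arange(J)) & 1).astype(float)  # (P, J)

    p = np.full(J, init_pq)
    q = np.full(J, init_pq)
    W_pat = np.zeros(len(patterns))
    ll_trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # E-step on patterns
        log_a = np.log(f) + votes @ np.log(p) + (1 - votes) @ np.log1p(-p)
        log_b = np.log1p(-f) + votes @ np.log1p(-q) + (1 - votes) @ np.log(q)
        m = np.maximum(log_a, log_b)
        denom = np.exp(log_a - m) + np.exp(log_b - m)
        W_new = np.exp(log_a - m) / denom
        ll_trace.append(float(np.sum(counts * (m + np.log(denom)))))

        delta = float(np.max(np.abs(W_new - W_pat)))
        W_pat = W_new
        # M-step
        wc = W_pat * counts
        total_w = wc.sum()
        total_nw = ((1 - W_pat) * counts).sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            p_new = (votes.T @ wc) / total_w if total_w > 0 else p
            q_new = ((1 - votes).T * counts * (1 - W_pat)).sum(axis=1) / total_nw \
                if total_nw > 0 else q
        eps = 1e-12
        p = np.clip(p_new, eps, 1 - eps)
        q = np.clip(q_new, eps, 1 - eps)
        if iterations > 1 and delta < tol:
            converged = True
            break

    W_vox = W_pat[np.searchsorted(patterns, codes)]
    consensus = first.with_values(W_vox.reshape(first.shape).astype(np.float32))
    return StapleResult(
        consensus=consensus,
        per_rater=[(float(pj), float(qj)) for pj, qj in zip(p, q)],
        iterations=iterations,
        converged=converged,
        log_likelihood=ll_trace,
    )


def fuse_folds(fold_masks: list[Volume3D], threshold: float = 0.5, **kwargs) -> Volume3D:
    """STAPLE the binary outputs of the k fold sub-models; threshold at 0.5."""
    result = staple(fold_masks, **kwargs)
    return result.consensus.with_values(
        (result.consensus.values >= threshold).astype(np.uint8)
    )


def ensemble_combine(
    variant_masks: list[Volume3D], rule: str = "staple", threshold: float = 0.5
) -> Volume3D:
    """Combine the three variant outputs (Orig, Vess, LDim) into the ensemble.

    ``rule='staple'`` runs STAPLE + threshold (degenerates to majority for
    symmetric rater qualities); ``rule='majority'`` is a plain vote.
    """
    if len(variant_masks) != 3:
        raise ValueError(f"ensemble expects 3 variant masks, got {len(variant_masks)}")
    if rule == "majority":
        first = variant_masks[0]
        for m in variant_masks[1:]:
            first.require_same_grid(m, "ensemble masks")
        votes = sum(m.values.astype(np.int32) for m in variant_masks)
        return first.with_values((votes >= 2).astype(np.uint8))
    if rule != "staple":
        raise ValueError(f"rule must be 'staple' or 'majority', got {rule!r}")
    result = staple(variant_masks)
    return result.consensus.with_values(
        (result.consensus.values >= threshold).astype(np.uint8)
    )
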