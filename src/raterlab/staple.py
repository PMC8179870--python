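"""Binary STAPLE label fusion via expectation-maximisation.

Simultaneous Truth And Performance Level Estimation treats the unknown true
segmentation ``T`` as a latent binary field and each rater ``j`` as a
noisy channel with sensitivity ``p_j = P(D_j=1 | T=1)`` and specificity
``q_j = P(D_j=0 | T=0)``.  With a spatially constant foreground prior ``f``,
EM alternates:

E-step (voxel ``i``):
    ``W_i = f a_i / (f a_i + (1-f) b_i)``,
    ``a_i = prod_j p_j^{d_ij} (1-p_j)^{1-d_ij}``,
    ``b_i = prod_j (1-q_j)^{d_ij} q_j^{1-d_ij}``

M-step:
    ``p_j = sum_i W_i d_ij / sum_i W_i``,
    ``q_j = sum_i (1-W_i)(1-d_ij) / sum_i (1-W_i)``

Iteration stops when the largest change over all (p_j, q_j) drops below
``tol``.  The computation is restricted to a bounding box around the union
of the rater masks (dilated by a voxel margin); outside it the posterior
is fixed to 0, which keeps the background prior from being dominated by
empty field-of-view and degrading the performance estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .mask_io import LabelVolume, require_same_geometry
from .metrics import (
    MetricRecord,
    average_hausdorff,
    dice,
    hausdorff,
)

logger = logging.getLogger("raterlab")


@dataclass
class ConsensusResult:
    """STAPLE output: posterior truth probability and per-rater performance."""

    posterior: np.ndarray  # reals in [0,1], full volume shape
    consensus_mask: LabelVolume
    per_rater: list[tuple[str, float, float]]  # (rater_id, p_j, q_j)
    n_iterations: int
    converged: bool
    threshold: float = 0.5
    trace: list[dict] = field(default_factory=list)

    @property
    def sensitivities(self) -> dict[str, float]:
        return {r: p for r, p, _ in self.per_rater}

    @property
    def specificities(self) -> dict[str, float]:
        return {r: q for r, _, q in self.per_rater}


def _bounding_slices(
    union: np.ndarray, margin: int
) -> tuple[slice, slice, slice]:
    idx = np.nonzero(union)
    return tuple(
        slice(
            max(int(ax.min()) - margin, 0),
            min(int(ax.max()) + margin + 1, union.shape[k]),
        )
        for k, ax in enumerate(idx)
    )


def staple(
    masks: list[LabelVolume] | dict[str, LabelVolume],
    prior: float | str = "sample-mean",
    tol: float = 1e-7,
    max_iter: int = 100,
    threshold: float = 0.5,
    init: float = 0.99999,
    bbox_margin: int = 10,
    keep_trace: bool = False,
) -> ConsensusResult:
    """Estimate the consensus segmentation of >=2 co-registered raters.

    Parameters
    ----------
    masks
        Rater masks with identical geometry, each nonempty.  A dict maps
        rater id -> mask; a list gets ids ``"r0"``, ``"r1"``, ...
    prior
        Foreground prior ``f``: ``"sample-mean"`` (mean foreground fraction
        across raters within the bounding box) or a constant in (0, 1).
    threshold
        Posterior cut for the consensus mask; ties (posterior ==
        threshold) count as foreground for determinism.
    """
    if isinstance(masks, dict):
        rater_ids = list(masks.keys())
        mask_list = list(masks.values())
    else:
        rater_ids = [f"r{j}" for j in range(len(masks))]
        mask_list = list(masks)
    if len(mask_list) < 2:
        raise ValueError("STAPLE needs at least 2 masks")
    require_same_geometry(*mask_list)
    for rid, m in zip(rater_ids, mask_list):
        if m.n_foreground == 0:
            raise ValueError(f"STAPLE input mask for rater {rid} is empty")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")

    stack = np.stack([m.voxels for m in mask_list])  # (J, nx, ny, nz)
    union = stack.any(axis=0)
    box = _bounding_slices(union, bbox_margin)
    d = stack[(slice(None),) + box].reshape(len(mask_list), -1).astype(float)
    n_raters, _ = d.shape

    if prior == "sample-mean":
        f = float(d.mean())
    else:
        f = float(prior)
        if not (0.0 < f < 1.0):
            raise ValueError(f"prior must lie in (0,1), got {f}")
    if not (0.0 < f < 1.0):
        raise ValueError(
            "degenerate input: sample-mean prior is 0 or 1 "
            "(all masks empty or all full within the bounding box)"
        )

    eps = np.finfo(float).tiny
    p = np.full(n_raters, init)
    q = np.full(n_raters, init)
    trace: list[dict] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step
        a = np.prod(np.where(d == 1, p[:, None], 1 - p[:, None]), axis=0)
        b = np.prod(np.where(d == 1, 1 - q[:, None], q[:, None]), axis=0)
        w = f * a / np.maximum(f * a + (1 - f) * b, eps)
        # M-step
        sw = w.sum()
        swc = (1 - w).sum()
        p_new = (w[None, :] * d).sum(axis=1) / max(sw, eps)
        q_new = ((1 - w)[None, :] * (1 - d)).sum(axis=1) / max(swc, eps)
        delta = max(
            np.abs(p_new - p).max(initial=0.0),
            np.abs(q_new - q).max(initial=0.0),
        )
        p, q = p_new, q_new
        if keep_trace:
            trace.append(
                {"iteration": n_iter, "p": p.tolist(), "q": q.tolist(),
                 "max_change": float(delta)}
            )
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"STAPLE did not converge in {max_iter} iterations "
            f"(last parameter change {delta:.3g})",
            stacklevel=2,
        )

    posterior = np.zeros(mask_list[0].shape, dtype=float)
    posterior[box] = w.reshape(posterior[box].shape)
    consensus = LabelVolume(posterior >= threshold, mask_list[0].spacing)
    logger.debug(
        "STAPLE converged=%s after %d iterations (prior f=%.4f)",
        converged, n_iter, f,
    )
    return ConsensusResult(
        posterior=posterior,
        consensus_mask=consensus,
        per_rater=[
            (rid, float(pj), float(qj))
            for rid, pj, qj in zip(rater_ids, p, q)
        ],
        n_iterations=n_iter,
        converged=converged,
        threshold=threshold,
        trace=trace,
    )


def compare_to_consensus(
    mask: LabelVolume,
    consensus: ConsensusResult,
    metric: str,
    case_id: str = "",
    structure: str = "",
    rater_id: str = "",
    group: str = "",
    units: str = "voxels",
    **metric_kwargs,
) -> MetricRecord:
    """Score one rater's mask against the STAPLE consensus mask."""
    ref = consensus.consensus_mask
    require_same_geometry(mask, ref)
    if metric == "DSC":
        value, rec_units = dice(mask, ref), "dimensionless"
    elif metric == "HD":
        value, rec_units = hausdorff(mask, ref, units=units, **metric_kwargs), units
    elif metric == "AHD":
        value, rec_units = (
            average_hausdorff(mask, ref, units=units, **metric_kwargs),
            units,
        )
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return MetricRecord(
        case_id=case_id,
        structure=structure,
        region="whole",
        frame=f"consensus({rater_id})",
        metric=metric,
        value=value,
        units=rec_units,
        rater_a=rater_id,
        group=group,
    )
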