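"""Protein-centric CAFA-style evaluation: Fmax and micro AUPR.

Fmax is the maximum over a threshold grid of the harmonic mean of
protein-averaged precision and recall.  At threshold tau, precision
averages TP/predicted over the N(tau) proteins with at least one score
>= tau; recall averages TP/true over all evaluated proteins.  Proteins
with no true annotation in the evaluated ontology are excluded (the
protein-centric convention; recall is undefined for them).

AUPR here is the micro (pair-flattened) average precision over all
(protein, term) cells, with tied scores handled as one group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import AnnotationMatrix, PredictionMatrix, ValidationError

__all__ = [
    "EvaluationReport",
    "precision_recall_at_threshold",
    "fmax",
    "micro_aupr",
    "evaluate",
    "THRESHOLD_GRID",
]

THRESHOLD_GRID = np.round(np.arange(0, 101) / 100.0, 2)  # 0.00 .. 1.00


@dataclass
class EvaluationReport:
    fmax: float
    tau_star: float
    aupr: float
    n_proteins: int
    threshold_table: list[tuple[float, float | None, float, int]] = field(
        default_factory=list
    )  # (tau, pr or None, rc, N(tau))
    subsets: dict[str, "EvaluationReport"] | None = None
    aupr_flavor: str = "micro (pair-flattened average precision)"


def _as_arrays(Y, S) -> tuple[np.ndarray, np.ndarray]:
    Ym = Y.Y if isinstance(Y, AnnotationMatrix) else np.asarray(Y)
    Sm = S.S if isinstance(S, PredictionMatrix) else np.asarray(S)
    if Ym.shape != Sm.shape:
        raise ValidationError("truth and prediction matrices must share shape")
    return Ym.astype(bool), np.asarray(Sm, dtype=np.float64)


def _annotated_only(Y: np.ndarray, S: np.ndarray):
    keep = Y.any(axis=1)
    return Y[keep], S[keep]


def precision_recall_at_threshold(Y, S, tau: float):
    """Protein-averaged precision and recall at one threshold.

    Returns ``(pr, rc, n_tau)``; ``pr`` is None when no protein makes a
    prediction at ``tau`` (flagged missing, not zero-filled).
    """
    Ym, Sm = _as_arrays(Y, S)
    Ym, Sm = _annotated_only(Ym, Sm)
    if Ym.shape[0] == 0:
        raise ValidationError("no annotated proteins to evaluate")
    pred = Sm >= tau
    tp = (pred & Ym).sum(axis=1)
    n_pred = pred.sum(axis=1)
    n_true = Ym.sum(axis=1)
    has_pred = n_pred > 0
    n_tau = int(has_pred.sum())
    pr = float((tp[has_pred] / n_pred[has_pred]).mean()) if n_tau else None
    rc = float((tp / n_true).mean())
    return pr, rc, n_tau


def fmax(Y, S, grid=THRESHOLD_GRID) -> tuple[float, float]:
    """Maximum harmonic mean of precision and recall over the threshold
    grid; returns (Fmax, smallest maximizing tau)."""
    best, best_tau = None, None
    for tau in grid:
        pr, rc, _ = precision_recall_at_threshold(Y, S, float(tau))
        if pr is None or pr + rc == 0:
            continue
        f1 = 2 * pr * rc / (pr + rc)
        if best is None or f1 > best:
            best, best_tau = f1, float(tau)
    if best is None:
        raise ValidationError("no threshold yields any prediction")
    return best, best_tau


def micro_aupr(Y, S) -> float:
    """Pair-flattened average precision.

    All (protein, term) cells are ranked by score descending; AP sums,
    over score groups, the group's true positives times the precision at
    the end of the group, divided by the total positives.
    """
    Ym, Sm = _as_arrays(Y, S)
    y = Ym.ravel()
    s = Sm.ravel()
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValidationError("micro AUPR undefined without positive pairs")
    order = np.argsort(-s, kind="stable")
    y, s = y[order], s[order]
    ap = 0.0
    cum_tp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        tp_group = int(y[i:j].sum())
        cum_tp += tp_group
        precision = cum_tp / j  # group-level: precision at the end of the tie group
        ap += tp_group * precision
        i = j
    return ap / n_pos


def evaluate(Y, S, subset_tags: dict[str, str] | None = None) -> EvaluationReport:
    """Full report: Fmax, micro AUPR and the per-threshold table, plus
    identical sub-reports per subset tag class when tags are supplied."""
    Ym, Sm = _as_arrays(Y, S)
    Ya, Sa = _annotated_only(Ym, Sm)
    table = []
    for tau in THRESHOLD_GRID:
        pr, rc, n_tau = precision_recall_at_threshold(Ya, Sa, float(tau))
        table.append((float(tau), pr, rc, n_tau))
    f, tau_star = fmax(Ya, Sa)
    report = EvaluationReport(
        fmax=f,
        tau_star=tau_star,
        aupr=micro_aupr(Ya, Sa),
        n_proteins=Ya.shape[0],
        threshold_table=table,
    )
    if subset_tags is not None:
        if not (isinstance(Y, AnnotationMatrix) and isinstance(S, PredictionMatrix)):
            raise ValidationError("subset evaluation needs catalog-bearing matrices")
        unknown = [p for p in subset_tags if p not in S.catalog]
        if unknown:
            raise ValidationError(f"subset tags reference unknown proteins: {unknown[:5]}")
        report.subsets = {}
        for tag in sorted(set(subset_tags.values())):
            rows = [S.catalog.index[p] for p, t in subset_tags.items() if t == tag]
            ys, ss = Ym[rows], Sm[rows]
            if not ys.any():
                continue
            ys, ss = _annotated_only(ys, ss)
            f_s, tau_s = fmax(ys, ss)
            report.subsets[tag] = EvaluationReport(
                fmax=f_s,
                tau_star=tau_s,
                aupr=micro_aupr(ys, ss),
                n_proteins=ys.shape[0],
            )
    return report
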