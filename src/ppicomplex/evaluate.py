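"""Affinity-score matching of predicted against reference complexes.

A prediction B matches a reference A when

    aff(A, B) = |A ∩ B|² / (|A| · |B|) ≥ ω        (default ω = 0.2)

Matching is existential on each side: R_hit counts references matched by
at least one prediction, C_hit counts predictions matched by at least
one reference.  Recall = R_hit/|R|, Precision = C_hit/|C|, F1 their
harmonic mean.  Both sides are filtered to complexes of size ≥ 3 before
counting, mirroring standard practice with MIPS/CYC2008/CORUM references.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph_io import ComplexSet

__all__ = ["EvaluationResult", "affinity", "match_counts", "evaluate"]


@dataclass(frozen=True)
class EvaluationResult:
    recall: float
    precision: float
    f1: float
    r_hit: int
    c_hit: int
    n_ref: int
    n_pred: int
    omega: float

    def as_dict(self) -> dict[str, float | int]:
        return {
            "n_pred": self.n_pred, "n_ref": self.n_ref,
            "r_hit": self.r_hit, "c_hit": self.c_hit,
            "recall": self.recall, "precision": self.precision,
            "f1": self.f1, "omega": self.omega,
        }


def affinity(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """Overlap affinity |A∩B|²/(|A|·|B|) ∈ [0, 1]; 1 iff A = B."""
    if not a or not b:
        raise ValueError("affinity requires non-empty sets")
    inter = len(set(a) & set(b))
    return inter * inter / (len(a) * len(b))


def match_counts(pred: ComplexSet, ref: ComplexSet, omega: float) -> tuple[int, int]:
    """(r_hit, c_hit): complexes on each side matched at affinity ≥ omega.

    Each complex counts at most once on its own side, however many
    partners it matches.
    """
    if not 0.0 < omega <= 1.0:
        raise ValueError(f"omega must be in (0, 1], got {omega}")
    preds = list(pred)
    refs = list(ref)
    r_hit = sum(1 for r in refs if any(affinity(r, c) >= omega for c in preds))
    c_hit = sum(1 for c in preds if any(affinity(c, r) >= omega for r in refs))
    return r_hit, c_hit


def evaluate(pred: ComplexSet, ref: ComplexSet, omega: float = 0.2,
             min_size: int = 3) -> EvaluationResult:
    """Recall/precision/F1 of predictions against a reference set.

    Both sides are filtered to complexes of size ≥ ``min_size`` first;
    an empty side yields 0 for the corresponding rate.
    """
    pred_f = pred.filter_min_size(min_size)
    ref_f = ref.filter_min_size(min_size)
    r_hit, c_hit = match_counts(pred_f, ref_f, omega)
    recall = r_hit / len(ref_f) if len(ref_f) else 0.0
    precision = c_hit / len(pred_f) if len(pred_f) else 0.0
    f1 = (2 * recall * precision / (recall + precision)) if (recall + precision) else 0.0
    return EvaluationResult(
        recall=recall, precision=precision, f1=f1,
        r_hit=r_hit, c_hit=c_hit,
        n_ref=len(ref_f), n_pred=len(pred_f), omega=omega,
    )
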