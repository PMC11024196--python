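"""TP2-corrected precision/recall/F with exact binomial confidence intervals.

The truth set is assumed incomplete, so calls unmatched by it (tentative
FPs) are re-validated on a random sample; the validated fraction scales up to
an estimated count of true positives hidden among the initial FPs (TP2).
Metrics are then::

    Pr = (TP1 + TP2) / Call x 100
    Rc = (TP1 + TP2) / Ref  x 100     (Ref raised to TP1+TP2 if exceeded)
    F  = Pr x Rc x 2 x 0.01 / (Pr + Rc)

TP1 is the count of calls matching the truth set, Call the total number of
calls, and Ref the truth count.  F is the harmonic mean of Pr/100 and Rc/100.
Uncertainty from sampling only ``n`` of the tentative FPs is carried as an
exact (Clopper-Pearson) binomial interval on the validated proportion and
propagated into Pr/Rc by substituting the interval endpoints for TP2.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from scipy.stats import binomtest

from .variants import VariantCall

log = logging.getLogger(__name__)

#: indel size bins (bp), as used for size-resolved insertion/deletion reports
INDEL_BINS: list[tuple[int, int]] = [
    (1, 2), (3, 5), (6, 10), (11, 20), (21, 30), (31, 40), (41, 50),
]
#: default SV size bins (bp); the upper bin is open-ended
SV_BINS: list[tuple[int, Optional[int]]] = [
    (50, 99), (100, 199), (200, 499), (500, 999), (1000, None),
]


def _bin_label(low: int, high: Optional[int]) -> str:
    return f"{low}-{high}" if high is not None else f">={low}"


def indel_bin_labels() -> list[str]:
    return [_bin_label(lo, hi) for lo, hi in INDEL_BINS]


def sv_bin_labels(sv_bins: Optional[list] = None) -> list[str]:
    return [_bin_label(lo, hi) for lo, hi in (sv_bins or SV_BINS)]


def assign_size_bin(
    v: VariantCall, sv_bins: Optional[list[tuple[int, Optional[int]]]] = None
) -> str:
    """Size-bin label for a variant (``"SNV"`` for SNVs)."""
    if v.vclass == "SNV":
        return "SNV"
    bins = INDEL_BINS if v.scale == "indel" else (sv_bins or SV_BINS)
    for low, high in bins:
        if v.size >= low and (high is None or v.size <= high):
            return _bin_label(low, high)
    return _bin_label(*bins[-1])  # oversized: clamp into the last bin


@dataclass
class EvaluationMetrics:
    """Counts and TP2-corrected precision/recall/F for one evaluation group."""

    tp1: int
    tp2: float
    n_call: int
    n_ref: int
    n_ref_adjusted: float
    precision: float  # percent
    recall: float  # percent
    f_measure: float  # 0-1
    precision_ci: Optional[tuple[float, float]] = None
    recall_ci: Optional[tuple[float, float]] = None


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided CI for a binomial proportion."""
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"invalid successes/trials: k={k}, n={n}")
    ci = binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return (ci.low, ci.high)


def estimate_tp2(
    n_initial_fp: int,
    n_validated_tp: int,
    n_sampled: int,
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Scale the validated-TP proportion up to the initial-FP pool.

    Returns ``(tp2, (low, high))`` where tp2 = n_initial_fp x k/n and the
    interval is the exact binomial CI on the proportion k/n.  With nothing
    sampled the estimate degenerates to 0 with a vacuous [0, 1] interval.
    """
    if n_sampled == 0:
        if n_initial_fp > 0:
            log.warning("estimate_tp2: no variants sampled; TP2 set to 0")
        return 0.0, (0.0, 1.0)
    if not 0 <= n_validated_tp <= n_sampled <= max(n_initial_fp, n_sampled):
        raise ValueError("need 0 <= n_validated_tp <= n_sampled <= n_initial_fp")
    tp2 = n_initial_fp * n_validated_tp / n_sampled
    return tp2, binomial_ci(n_validated_tp, n_sampled, level)


def _pr_rc_f(tp: float, n_call: int, n_ref: int) -> tuple[float, float, float, float]:
    pr = tp / n_call * 100 if n_call else 0.0
    ref_adj = max(float(n_ref), tp)
    rc = tp / ref_adj * 100 if ref_adj else 0.0
    f = pr * rc * 2 * 0.01 / (pr + rc) if pr + rc > 0 else 0.0
    return pr, rc, f, ref_adj


def compute_metrics(
    tp1: int,
    tp2: float,
    n_call: int,
    n_ref: int,
    tp2_ci: Optional[tuple[float, float]] = None,
) -> EvaluationMetrics:
    """Compute TP2-corrected precision, recall and F for one group.

    ``tp2_ci`` is an interval on the TP2 *count*; confidence intervals for
    Pr/Rc are obtained by substituting its endpoints into the same formulas
    (including the Ref adjustment).  TP2 is carried unrounded.
    """
    if n_call < tp1:
        raise ValueError(f"n_call={n_call} < tp1={tp1}")
    if n_call == 0:
        log.warning("compute_metrics: empty call set; all metrics zero")
    pr, rc, f, ref_adj = _pr_rc_f(tp1 + tp2, n_call, n_ref)
    pr_ci = rc_ci = None
    if tp2_ci is not None:
        lo_pr, lo_rc, _, _ = _pr_rc_f(tp1 + tp2_ci[0], n_call, n_ref)
        hi_pr, hi_rc, _, _ = _pr_rc_f(tp1 + tp2_ci[1], n_call, n_ref)
        pr_ci = (min(lo_pr, hi_pr), max(lo_pr, hi_pr))
        rc_ci = (min(lo_rc, hi_rc), max(lo_rc, hi_rc))
    return EvaluationMetrics(
        tp1=tp1, tp2=tp2, n_call=n_call, n_ref=n_ref, n_ref_adjusted=ref_adj,
        precision=pr, recall=rc, f_measure=f,
        precision_ci=pr_ci, recall_ci=rc_ci,
    )


def size_binned_report(
    results: Iterable,
    truth: Iterable[VariantCall] = (),
    str_rs=None,
    segdup_rs=None,
    sv_bins: Optional[list[tuple[int, Optional[int]]]] = None,
) -> pd.DataFrame:
    """Per size-bin x stratum x class table of TP1/tFP counts and metrics.

    Bins with zero calls appear as zero rows rather than being omitted.
    Truth variants (for per-bin Ref counts) are stratified with the same
    region sets when given.  Per-bin precision/recall here use TP1 only;
    the TP2 correction applies at the per-class level where tFP sampling is
    performed.
    """
    from .matching import class_label
    from .regions import RegionSet, classify_position

    str_rs = (str_rs or RegionSet(label="STR")).coalesced()
    segdup_rs = (segdup_rs or RegionSet(label="SegDup")).coalesced()

    rows: dict[tuple, dict[str, float]] = {}

    def row(cls: str, size_bin: str, stratum: str) -> dict[str, float]:
        return rows.setdefault(
            (cls, size_bin, stratum),
            {"tp1": 0, "tfp": 0, "n_call": 0, "n_ref": 0},
        )

    classes_seen: set[str] = set()
    for r in results:
        cls = class_label(r.call)
        classes_seen.add(cls)
        rec = row(cls, r.size_bin, r.stratum)
        rec["n_call"] += 1
        rec["tp1" if r.status == "TP" else "tfp"] += 1
    for t in truth:
        cls = class_label(t)
        classes_seen.add(cls)
        stratum = classify_position(t, str_rs, segdup_rs)
        row(cls, assign_size_bin(t, sv_bins), stratum)["n_ref"] += 1

    # materialize empty bins for every class/stratum seen
    for cls in classes_seen:
        if cls == "SNV":
            bins = ["SNV"]
        elif cls in ("ins", "del"):
            bins = indel_bin_labels()
        else:
            bins = sv_bin_labels(sv_bins)
        for size_bin in bins:
            for stratum in ("nonrepeat", "STR", "SegDup"):
                row(cls, size_bin, stratum)

    records = []
    for (cls, size_bin, stratum), rec in sorted(rows.items()):
        pr, rc, f, _ = _pr_rc_f(rec["tp1"], int(rec["n_call"]), int(rec["n_ref"]))
        records.append(
            {
                "class": cls, "size_bin": size_bin, "stratum": stratum,
                "tp1": int(rec["tp1"]), "tfp": int(rec["tfp"]),
                "n_call": int(rec["n_call"]), "n_ref": int(rec["n_ref"]),
                "precision": pr, "recall": rc, "f_measure": f,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["class", "size_bin", "stratum", "tp1", "tfp", "n_call",
                 "n_ref", "precision", "recall", "f_measure"],
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def write_report(report: dict, path: str, format: str = "json") -> None:
    """Serialize a report (counts, metrics, parameters, seeds) to disk.

    ``json`` writes the full nested report; ``tsv`` writes the tabular
    per-stratum/class/bin section (key ``"size_binned"`` when present,
    otherwise a flat table of the per-group metrics).
    """
    if format == "json":
        with open(path, "w") as out:
            json.dump(_jsonable(report), out, indent=2, sort_keys=True)
            out.write("\n")
    elif format == "tsv":
        table = report.get("size_binned")
        if isinstance(table, pd.DataFrame):
            table.to_csv(path, sep="\t", index=False)
        else:
            rows = []
            for group, m in report.get("metrics", {}).items():
                rec = {"group": group}
                rec.update(_jsonable(m))
                rows.append(rec)
            pd.DataFrame.from_records(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")
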