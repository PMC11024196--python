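"""End-to-end benchmark composition: normalize -> deduplicate -> match ->
sample -> re-validate -> TP2-corrected metrics.

This is the layer the command-line interface and the examples drive; each
stage is usable on its own through its module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .matching import (MatchParams, MatchResult, class_label, evaluate_callset)
from .metrics import (EvaluationMetrics, compute_metrics, estimate_tp2,
                      size_binned_report)
from .regions import RegionSet, classify_position
from .revalidation import (AlignmentEvidence, EvidenceParams, SampledValidation,
                           sample_group_key, sample_tfp, stratum_group,
                           validate_sample, validate_with_labels)
from .truthset import TruthSet
from .variants import CallSet, dup_to_ins, deduplicate

log = logging.getLogger(__name__)

REGION_GROUPS = ("nonrepeat", "repeat", "genome")


@dataclass
class BenchmarkReport:
    """Everything one evaluation run produced."""

    results: list[MatchResult]
    metrics: dict[str, EvaluationMetrics]  # "class/region" -> metrics
    validations: dict[tuple, SampledValidation]
    size_binned: pd.DataFrame
    params: dict

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "validations": {"/".join(k): v for k, v in self.validations.items()},
            "size_binned": self.size_binned,
            "params": self.params,
        }


def _region_groups_of(stratum: Optional[str]) -> tuple[str, ...]:
    return (stratum_group(stratum), "genome")


def run_benchmark(
    calls: CallSet,
    truth: TruthSet,
    str_rs: Optional[RegionSet] = None,
    segdup_rs: Optional[RegionSet] = None,
    match_params: MatchParams = MatchParams(),
    evidence: Optional[AlignmentEvidence] = None,
    labels: Optional[dict[str, bool]] = None,
    evidence_params: EvidenceParams = EvidenceParams(),
    n_sample: int = 50,
    seed: int = 0,
    dedup: bool = True,
) -> BenchmarkReport:
    """Run the full evaluation of one call set against one truth set.

    DUP calls are converted to INS on both sides, the call set is
    deduplicated, every call is matched by its class-specific criterion and
    stratified (STR priority over SegDup), tentative FPs are sampled per
    region group x class (x indel size range) and re-validated against
    ``evidence`` (long-read alignments) or ``labels`` (synthetic ground
    truth); without either, TP2 is 0.  Metrics are reported per class for
    nonrepeat / repeat / whole-genome groups.
    """
    str_rs = (str_rs or RegionSet(label="STR")).coalesced()
    segdup_rs = (segdup_rs or RegionSet(label="SegDup")).coalesced()

    norm_calls = CallSet(
        calls=[dup_to_ins(c) for c in calls],
        read_type=calls.read_type, label=calls.label,
    )
    if dedup:
        norm_calls = deduplicate(norm_calls)
    norm_truth = [dup_to_ins(t) for t in truth]

    results = evaluate_callset(norm_calls, norm_truth, str_rs, segdup_rs,
                               match_params)

    tfp = [r for r in results if r.status == "tFP"]
    n_initial: dict[tuple, int] = {}
    for r in tfp:
        key = sample_group_key(r)
        n_initial[key] = n_initial.get(key, 0) + 1
    samples = sample_tfp(tfp, n=n_sample, seed=seed)
    if evidence is not None:
        validations = validate_sample(samples, evidence, n_initial, evidence_params)
    elif labels is not None:
        validations = validate_with_labels(samples, labels, n_initial)
    else:
        validations = {}

    # TP2 point estimate and CI endpoints per sampling group
    tp2_by_group: dict[tuple, tuple[float, float, float]] = {}
    for key, v in validations.items():
        est, (plo, phi) = estimate_tp2(v.n_initial_fp, v.n_validated_tp, v.n_sampled)
        tp2_by_group[key] = (est, v.n_initial_fp * plo, v.n_initial_fp * phi)

    # truth counts per class x region group
    ref_counts: dict[tuple[str, str], int] = {}
    for t in norm_truth:
        cls = class_label(t)
        stratum = classify_position(t, str_rs, segdup_rs)
        for group in _region_groups_of(stratum):
            ref_counts[(cls, group)] = ref_counts.get((cls, group), 0) + 1

    metrics: dict[str, EvaluationMetrics] = {}
    groups = sorted(
        {(class_label(r.call), g) for r in results for g in _region_groups_of(r.stratum)}
        | set(ref_counts)
    )
    for cls, region in groups:
        in_group = [
            r for r in results
            if class_label(r.call) == cls and region in _region_groups_of(r.stratum)
        ]
        tp1 = sum(1 for r in in_group if r.status == "TP")
        n_call = len(in_group)
        tp2 = lo = hi = 0.0
        for key, (est, e_lo, e_hi) in tp2_by_group.items():
            if key[1] != cls:
                continue
            if region != "genome" and key[0] != region:
                continue
            tp2 += est
            lo += e_lo
            hi += e_hi
        metrics[f"{cls}/{region}"] = compute_metrics(
            tp1, tp2, n_call, ref_counts.get((cls, region), 0),
            (lo, hi) if validations else None,
        )

    table = size_binned_report(results, norm_truth, str_rs, segdup_rs)
    params = {
        "match_params": match_params,
        "evidence_params": evidence_params if (evidence or labels) else None,
        "n_sample": n_sample,
        "seed": seed,
        "dedup": dedup,
        "n_calls_input": len(calls),
        "n_calls_evaluated": len(norm_calls),
        "n_truth": len(truth),
        "validation_mode": (
            "alignment" if evidence is not None
            else "labels" if labels is not None else "none"
        ),
    }
    return BenchmarkReport(
        results=results, metrics=metrics, validations=validations,
        size_binned=table, params=params,
    )
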