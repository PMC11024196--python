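"""Replicated statistical experiments on synthetic call sets.

The headline experiment plants a truth set, degrades it into calls with a
chosen true precision and recall, hides part of the truth from the reference
set (as real curated truth sets miss variants), runs the full
match -> sample -> re-validate -> correct pipeline, and checks that the
confidence intervals on the corrected precision/recall cover the planted
values.  Re-validation uses the generator's ground-truth labels, so the only
stochastic error is the one the CI is meant to quantify: adjudicating a
fixed-size sample of the tentative FPs.

Recall here is defined against the reference-set denominator, the same
denominator the estimator uses: the known reference size is set to
``n_tp / r`` so the target recall is exactly ``r``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matching import MatchParams, evaluate_callset
from .metrics import compute_metrics, estimate_tp2
from .revalidation import sample_tfp, validate_with_labels
from .truthset import TruthSet, TruthVariant
from .variants import CallSet, VariantCall

log = logging.getLogger(__name__)


@dataclass
class RecoveryResult:
    precision_true: float
    recall_true: float
    n_reps: int
    coverage_pr: float  # fraction of replicates whose Pr CI covers 100 p
    coverage_rc: float
    mean_pr: float
    mean_rc: float


def _one_replicate(
    p: float,
    r: float,
    n_calls: int,
    n_sample: int,
    ref_fraction: float,
    rng: np.random.Generator,
    seed: int,
):
    """Build one synthetic instance and run the estimation pipeline.

    Insertion indels on an abstract coordinate axis: positions on a 600-bp
    grid (far beyond every matching tolerance) with small jitter, sizes
    6-49 bp so all tentative FPs fall in one sampling group.
    """
    n_tp = int(round(n_calls * p))
    n_fp = n_calls - n_tp
    n_known = int(round(n_tp / r))
    n_tp_known = int(round(ref_fraction * n_tp))
    n_tp_hidden = n_tp - n_tp_known

    n_slots = n_known + n_tp_hidden + n_fp
    slots = 1000 + 600 * rng.permutation(n_slots)
    known_pos = slots[:n_known]
    hidden_pos = slots[n_known:n_known + n_tp_hidden]
    fp_pos = slots[n_known + n_tp_hidden:]

    sizes_known = rng.integers(6, 50, size=n_known)
    truth = TruthSet(variants=[
        TruthVariant(call_id=f"t{i}", chrom="sim1", pos=int(known_pos[i]),
                     vclass="INS", size=int(sizes_known[i]), read_type="long",
                     source="sim", source_set="sim")
        for i in range(n_known)
    ])

    calls: list[VariantCall] = []
    labels: dict[str, bool] = {}

    def add(pos: int, size: int, label: bool) -> None:
        cid = f"c{len(calls)}"
        calls.append(VariantCall(
            call_id=cid, chrom="sim1", pos=int(pos), vclass="INS",
            size=int(size), read_type="long", source="sim",
        ))
        labels[cid] = label

    picked = rng.choice(n_known, size=n_tp_known, replace=False)
    jitter = rng.integers(-3, 4, size=n_tp_known)  # within 0.5 x size for >= 6 bp
    for j, i in enumerate(picked):
        add(known_pos[i] + jitter[j], sizes_known[i], True)
    for pos in hidden_pos:  # true variants absent from the reference set
        add(pos, int(rng.integers(6, 50)), True)
    for pos in fp_pos:
        add(pos, int(rng.integers(6, 50)), False)

    callset = CallSet(calls=calls, read_type="long", label="sim")
    results = evaluate_callset(callset, truth, params=MatchParams())
    tp1 = sum(1 for x in results if x.status == "TP")
    tfp = [x for x in results if x.status == "tFP"]
    n_initial = {}
    for x in tfp:
        key = ("nonrepeat", "ins", "6-50")
        n_initial[key] = n_initial.get(key, 0) + 1
    samples = sample_tfp(tfp, n=n_sample, seed=seed)
    validations = validate_with_labels(samples, labels, n_initial)
    tp2 = 0.0
    tp2_lo = tp2_hi = 0.0
    for v in validations.values():
        est, (plo, phi) = estimate_tp2(v.n_initial_fp, v.n_validated_tp, v.n_sampled)
        tp2 += est
        tp2_lo += v.n_initial_fp * plo
        tp2_hi += v.n_initial_fp * phi
    return compute_metrics(tp1, tp2, len(callset), n_known, (tp2_lo, tp2_hi))


def precision_recall_recovery(
    precision_true: float,
    recall_true: float,
    n_calls: int = 2000,
    n_reps: int = 200,
    n_sample: int = 50,
    ref_fraction: float = 0.8,
    seed: int = 1,
) -> RecoveryResult:
    """CI coverage of planted precision/recall over replicated benchmarks."""
    cover_pr = cover_rc = 0
    sum_pr = sum_rc = 0.0
    base = [seed, int(precision_true * 1000), int(recall_true * 1000)]
    for rep in range(n_reps):
        rng = np.random.default_rng(base + [rep])
        m = _one_replicate(
            precision_true, recall_true, n_calls, n_sample, ref_fraction,
            rng, seed=(seed * 100003 + rep) % (2**31),
        )
        assert m.precision_ci is not None and m.recall_ci is not None
        if m.precision_ci[0] <= 100 * precision_true <= m.precision_ci[1]:
            cover_pr += 1
        if m.recall_ci[0] <= 100 * recall_true <= m.recall_ci[1]:
            cover_rc += 1
        sum_pr += m.precision
        sum_rc += m.recall
    res = RecoveryResult(
        precision_true=precision_true, recall_true=recall_true, n_reps=n_reps,
        coverage_pr=cover_pr / n_reps, coverage_rc=cover_rc / n_reps,
        mean_pr=sum_pr / n_reps, mean_rc=sum_rc / n_reps,
    )
    log.info(
        "recovery p=%.2f r=%.2f: coverage Pr %.3f Rc %.3f (mean Pr %.1f Rc %.1f)",
        precision_true, recall_true, res.coverage_pr, res.coverage_rc,
        res.mean_pr, res.mean_rc,
    )
    return res
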