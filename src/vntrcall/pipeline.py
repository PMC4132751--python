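"""End-to-end orchestration: candidate filtering, confirmation
alignment, mapping, duplicate removal and genotyping, plus the
simulation-based accuracy evaluation.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import yaml

from . import calling
from .alignment import flank_align, profile_align, ws_pass
from .calling import GenotypeCall, call_locus
from .filters import (DEFAULT_SEED_SHAPE, build_seed_index, candidate_refs,
                      lcs_filter)
from .mapping import (CandidatePair, MappingSet, discard_conflicted_reads,
                      eliminate_pcr_duplicates, select_mappings)
from .profiles import Profile, TandemRepeat, profile_for_tr, revcomp
from .refset import SINGLETON, ReferenceSet
from .simulate import Haplotype, SimRead, TruthRecord

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable thresholds, with the published defaults."""

    lcs_min: float = 0.85
    len_diff_max: float = 0.10
    ws_min: float = 88.0
    flank_err_max: float = 0.10
    min_read_flank: int = 20
    ref_flank: int = 50
    flank_cap: Optional[int] = 50  # None = unrestricted
    min_support: int = 2
    seed_shape: str = DEFAULT_SEED_SHAPE
    min_seed_hits: int = 1
    band: int = 5
    rng_seed: int = 0
    platform: str = "454"  # simulator/error-model selection

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    """Artifacts of one mapping + calling run."""

    pairs: list[CandidatePair]
    mapping: MappingSet
    reads_per_ref: dict[str, list[tuple[str, str]]]
    read_trs_per_ref: dict[str, list[TandemRepeat]]
    calls: dict[str, GenotypeCall]
    counters: dict[str, int]


def score_pairs(refset: ReferenceSet, read_trs: Sequence[TandemRepeat],
                config: RunConfig,
                ref_profiles: Optional[dict[str, Profile]] = None
                ) -> tuple[list[CandidatePair], dict[str, int]]:
    """Run the filter and confirmation-alignment cascade.

    Returns every read-TR/ref-TR pair passing the spaced-seed, LCS,
    profile-WS and flank filters, with exact rational scores, plus
    per-stage counters.
    """
    counters = {"read_trs_in": len(read_trs), "read_trs_admissible": 0,
                "pairs_seed": 0, "pairs_lcs": 0, "pairs_ws": 0, "pairs_flank": 0}
    index = build_seed_index(refset.repeats, config.seed_shape)
    if ref_profiles is None:
        ref_profiles = {tr.id: profile_for_tr(tr) for tr in refset.repeats}
    pairs: list[CandidatePair] = []
    for rt in read_trs:
        if not rt.is_admissible(config.min_read_flank):
            continue
        counters["read_trs_admissible"] += 1
        cands = candidate_refs(rt, index, config.min_seed_hits)
        if not cands:
            continue
        rt_profile = profile_for_tr(rt)
        left = rt.left_flank[-config.flank_cap:] if config.flank_cap else rt.left_flank
        right = rt.right_flank[:config.flank_cap] if config.flank_cap else rt.right_flank
        for ref_id in sorted(cands):
            ref = refset.by_id[ref_id]
            counters["pairs_seed"] += 1
            if not lcs_filter(rt.pattern, ref.pattern, config.lcs_min,
                              config.len_diff_max):
                continue
            counters["pairs_lcs"] += 1
            res = profile_align(rt_profile, ref_profiles[ref_id], band=config.band)
            if not ws_pass(res, config.ws_min):
                continue
            counters["pairs_ws"] += 1
            if res.orientation == "forward":
                r_left, r_right = left, right
            else:
                r_left, r_right = revcomp(right), revcomp(left)
            fres = flank_align(r_left, r_right,
                               ref.left_flank[-config.ref_flank:],
                               ref.right_flank[:config.ref_flank],
                               flank_cap=config.flank_cap)
            if not fres.passes(config.flank_err_max):
                continue
            counters["pairs_flank"] += 1
            pairs.append(CandidatePair(
                read_id=rt.source[0], ordinal=rt.source[1], ref_id=ref_id,
                ws=res.ws_exact(), flank_rate=fres.rate_exact(),
                orientation=res.orientation, rotation=res.rotation,
            ))
    return pairs, counters


def genotype(refset: ReferenceSet, read_trs: Sequence[TandemRepeat],
             read_seqs: dict[str, str], config: RunConfig = RunConfig(),
             ref_profiles: Optional[dict[str, Profile]] = None
             ) -> PipelineResult:
    """Full mapping and genotyping of a read-TR set against a reference set."""
    pairs, counters = score_pairs(refset, read_trs, config, ref_profiles)
    mapping = select_mappings(pairs)
    read_lengths = {rid: len(seq) for rid, seq in read_seqs.items()}
    mapping = discard_conflicted_reads(mapping, read_lengths, refset.by_id)
    counters["read_trs_mapped"] = len(mapping.assignments)

    trs_by_id = {rt.source: rt for rt in read_trs}
    reads_per_ref: dict[str, list[tuple[str, str]]] = {}
    for read_tr_id, ref_id in mapping.assignments.items():
        reads_per_ref.setdefault(ref_id, []).append(
            (read_tr_id[0], read_seqs[read_tr_id[0]]))
    reads_per_ref = {r: sorted(v) for r, v in reads_per_ref.items()}
    deduped, dup_dropped = eliminate_pcr_duplicates(reads_per_ref)
    counters["pcr_duplicates"] = len(dup_dropped)

    read_trs_per_ref: dict[str, list[TandemRepeat]] = {}
    final_mapping = MappingSet(discarded=dict(mapping.discarded))
    kept_reads = {ref_id: {rid for rid, _ in rl} for ref_id, rl in deduped.items()}
    for read_tr_id, ref_id in mapping.assignments.items():
        if read_tr_id[0] in kept_reads.get(ref_id, set()):
            final_mapping.assignments[read_tr_id] = ref_id
            read_trs_per_ref.setdefault(ref_id, []).append(trs_by_id[read_tr_id])
        else:
            final_mapping.discarded[read_tr_id] = "pcr-duplicate"

    calls = {
        ref_id: call_locus(refset.by_id[ref_id], trs, config.min_support,
                           refset.category(ref_id))
        for ref_id, trs in sorted(read_trs_per_ref.items())
    }
    counters["refs_with_reads"] = len(read_trs_per_ref)
    counters["vntr_calls"] = sum(1 for c in calls.values() if c.is_vntr)
    return PipelineResult(pairs=pairs, mapping=final_mapping,
                          reads_per_ref=deduped,
                          read_trs_per_ref=read_trs_per_ref,
                          calls=calls, counters=counters)


# ---------------------------------------------------------------------------
# evaluation against simulator ground truth
# ---------------------------------------------------------------------------

def _genotypable(truth: TruthRecord, n_a: int, n_b: int, min_support: int) -> bool:
    """A locus is genotypable when enough ground-truth spanning read-TRs
    exist to support every allele it carries (the accuracy denominator)."""
    if truth.zygosity == "heterozygous":
        return n_a >= min_support and n_b >= min_support
    return n_a + n_b >= min_support


def evaluate(result: PipelineResult, refset: ReferenceSet,
             truth: Sequence[TruthRecord],
             origins: dict[tuple[str, int], str],
             reads: Sequence[SimRead],
             min_support: int = 2,
             singleton_only: bool = False) -> dict[str, float]:
    """Accuracy of mapping and genotype calling against planted truth.

    Read mapping sensitivity counts ground-truth read-TRs assigned to
    their source locus; precision counts assignments that are correct.
    Genotype sensitivity/specificity/PPV are computed per zygosity class
    over genotypable loci (enough spanning read-TRs to support each
    carried allele).  ``singleton_only`` restricts locus-level measures
    to singleton references.
    """
    truth_by_id = {t.ref_id: t for t in truth}
    hap_of_read = {r.id: r.haplotype for r in reads}
    hap_names = sorted({r.haplotype for r in reads}) or ["hapA", "hapB"]
    span_a: dict[str, int] = {}
    span_b: dict[str, int] = {}
    for (read_id, _), ref_id in origins.items():
        if hap_of_read.get(read_id) == hap_names[0]:
            span_a[ref_id] = span_a.get(ref_id, 0) + 1
        else:
            span_b[ref_id] = span_b.get(ref_id, 0) + 1

    assigned = result.mapping.assignments
    duplicates = {rt for rt, reason in result.mapping.discarded.items()
                  if reason == "pcr-duplicate"}
    n_true = sum(1 for rt in origins if rt not in duplicates)
    n_assigned = len(assigned)
    n_correct = sum(1 for rt, ref in assigned.items() if origins.get(rt) == ref)

    def keep(rid: str) -> bool:
        return not singleton_only or refset.category(rid) == SINGLETON

    per_class = {"unmodified": [0, 0], "homozygous": [0, 0],
                 "heterozygous": [0, 0]}  # [genotypable, correct]
    tp = fp = 0
    for t in truth:
        if not keep(t.ref_id):
            continue
        call = result.calls.get(t.ref_id)
        expected = {t.delta_a, t.delta_b}
        if call is not None and call.is_vntr:
            if set(call.deltas) == expected and t.zygosity != "unmodified":
                tp += 1
            else:
                fp += 1
        if not _genotypable(t, span_a.get(t.ref_id, 0), span_b.get(t.ref_id, 0),
                            min_support):
            continue
        stats = per_class[t.zygosity]
        stats[0] += 1
        if t.zygosity == "unmodified":
            ok = call is None or not call.is_vntr
        else:
            ok = (call is not None and call.is_vntr
                  and set(call.deltas) == expected)
        if ok:
            stats[1] += 1

    def ratio(num, den):
        return num / den if den else float("nan")

    return {
        "read_mapping_sensitivity": ratio(n_correct, n_true),
        "read_mapping_precision": ratio(n_correct, n_assigned),
        "unmodified_specificity": ratio(*reversed(per_class["unmodified"])),
        "homozygous_sensitivity": ratio(*reversed(per_class["homozygous"])),
        "heterozygous_sensitivity": ratio(*reversed(per_class["heterozygous"])),
        "vntr_ppv": ratio(tp, tp + fp),
        "n_genotypable_homozygous": per_class["homozygous"][0],
        "n_genotypable_heterozygous": per_class["heterozygous"][0],
        "n_vntr_calls": tp + fp,
    }
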