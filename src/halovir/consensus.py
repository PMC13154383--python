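"""Ensemble consensus of multiple virus predictors' contig calls.

The calls of several prediction tools are concatenated, exact duplicates
collapsed, name-variant duplicates (full-length contig plus a trimmed
provirus variant) reduced to the *shortest* sequence, and the survivors
filtered to contigs strictly longer than ``min_length_bp`` that were called
by at least ``min_tools`` distinct predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from halovir.io import strip_trim_suffix

logger = logging.getLogger("halovir")


class UnknownContigError(KeyError):
    """A predictor call references a contig absent from the assembly."""


@dataclass
class ConsensusRecord:
    """Outcome of deduplication + filtering for one contig base name."""

    base_name: str
    kept_contig_id: str
    kept_length_bp: int
    kept_sequence: str
    supporting_predictors: frozenset[str]
    passed: bool = False
    fail_reason: str = "none"  # none | too_short | insufficient_votes


def resolve_call_sequence(contig_id: str, contigs: dict[str, str],
                          delimiter: str = "||") -> str:
    """Sequence for a call id, slicing out a trim-suffix region if present."""
    if contig_id in contigs:
        return contigs[contig_id]
    base = strip_trim_suffix(contig_id, delimiter)
    if base not in contigs:
        raise UnknownContigError(f"call references unknown contig {contig_id!r}")
    suffix = contig_id[len(base) + len(delimiter):]
    try:
        start_s, end_s = suffix.split("_")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise UnknownContigError(
            f"call references unknown contig {contig_id!r} "
            f"(unparseable trim suffix {suffix!r})") from exc
    seq = contigs[base]
    if not 0 <= start < end <= len(seq):
        raise UnknownContigError(
            f"trim coordinates {start}_{end} outside contig {base!r}")
    return seq[start:end]


def dedupe_calls(calls: pd.DataFrame, contigs: dict[str, str],
                 delimiter: str = "||") -> list[ConsensusRecord]:
    """Collapse predictor calls to one record per contig base name.

    Exact duplicate sequences (same canonical strand) are collapsed first.
    Among the name-variants of one base contig the shortest sequence is
    retained, with ties broken lexicographically by call id; the supporting
    predictor set is the union over all variants.  The result is a function
    of the call *set* — input row order never matters.
    """
    variants: dict[str, dict[str, str]] = {}   # base -> call id -> sequence
    supporters: dict[str, set[str]] = {}
    for row in calls.itertuples(index=False):
        seq = resolve_call_sequence(row.contig_id, contigs, delimiter)
        base = strip_trim_suffix(row.contig_id, delimiter)
        variants.setdefault(base, {})[row.contig_id] = seq
        supporters.setdefault(base, set()).add(row.predictor)

    # exact-duplicate collapse across base names: keep the lexicographically
    # first base per sequence hash, merging supporter sets
    by_seq: dict[str, str] = {}
    merged_into: dict[str, str] = {}
    for base in sorted(variants):
        full = variants[base].get(base)
        if full is None:
            continue
        if full in by_seq:
            merged_into[base] = by_seq[full]
        else:
            by_seq[full] = base
    for dup, keep in merged_into.items():
        supporters[keep] |= supporters.pop(dup)
        variants[keep].update(variants.pop(dup))

    records = []
    for base in sorted(variants):
        # shortest variant wins; ties broken by call id for determinism
        kept_id, kept_seq = min(variants[base].items(),
                                key=lambda kv: (len(kv[1]), kv[0]))
        records.append(ConsensusRecord(
            base_name=base, kept_contig_id=kept_id,
            kept_length_bp=len(kept_seq), kept_sequence=kept_seq,
            supporting_predictors=frozenset(supporters[base])))
    return records


def consensus_filter(records: list[ConsensusRecord], min_length_bp: int = 10_000,
                     min_tools: int = 2) -> list[ConsensusRecord]:
    """Flag records passing the strict length and distinct-predictor vote.

    Returns the passing subset; every input record's ``passed`` and
    ``fail_reason`` fields are set in place.  A contig of exactly
    ``min_length_bp`` fails (the cut is strictly greater-than); the vote
    counts distinct predictors, not calls.
    """
    n_short = n_votes = 0
    passing = []
    for rec in records:
        if rec.kept_length_bp <= min_length_bp:
            rec.passed, rec.fail_reason = False, "too_short"
            n_short += 1
        elif len(rec.supporting_predictors) < min_tools:
            rec.passed, rec.fail_reason = False, "insufficient_votes"
            n_votes += 1
        else:
            rec.passed, rec.fail_reason = True, "none"
            passing.append(rec)
    logger.info("consensus: %d in, %d passed, %d too_short, %d insufficient_votes",
                len(records), len(passing), n_short, n_votes)
    return passing


def run_consensus(calls: pd.DataFrame, contigs: dict[str, str],
                  min_length_bp: int = 10_000, min_tools: int = 2,
                  delimiter: str = "||") -> list[ConsensusRecord]:
    """Dedupe then filter; the passing viral contig set."""
    return consensus_filter(dedupe_calls(calls, contigs, delimiter),
                            min_length_bp, min_tools)
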