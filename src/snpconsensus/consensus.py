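"""Consensus voting, frequency counting, and confidence scoring.

The final iteration's method calls form a vote matrix over the four
ensemble members (stepwise, ridge, lasso, Boruta); SNPs flagged by at
least three methods are the consensus "key SNPs".  Independently, every
significant/confirmed call across all methods and all iterations counts
toward a per-SNP frequency (at most one per method per iteration, so the
maximum with 4 methods and 4 iterations is 16), and the confidence score
is that frequency divided by methods x iterations; scores above 0.5 mark
likely true positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regression import ALL_METHODS, MethodCall

DEFAULT_MIN_METHODS = 3
DEFAULT_CONFIDENCE_THRESHOLD = 0.5


@dataclass
class VoteMatrix:
    """Boolean votes: one row per SNP with >= 1 final-iteration vote."""

    snp_ids: list[str]
    methods: tuple[str, ...]
    votes: np.ndarray  # (n_snps, n_methods) bool

    def n_votes(self, snp_id: str) -> int:
        return int(self.votes[self.snp_ids.index(snp_id)].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.votes, index=self.snp_ids,
                            columns=list(self.methods))


@dataclass
class FrequencyRecord:
    snp_id: str
    count: int
    by_iteration: dict[int, int]  # iteration -> number of methods voting


@dataclass
class ConfidenceScore:
    snp_id: str
    score: float
    is_true_positive_candidate: bool


@dataclass
class ConsensusReport:
    """Everything the pipeline reports for one phenotype."""

    phenotype: str
    iteration_records: list  # RFIterationRecord
    calls: list[MethodCall]
    votes: VoteMatrix
    key_snps: list[str]
    frequencies: list[FrequencyRecord]
    confidences: list[ConfidenceScore]
    n_methods: int = 4
    n_iterations: int = 4
    covariate_calls: list[MethodCall] = field(default_factory=list)
    config: dict = field(default_factory=dict)


def build_vote_matrix(calls: list[MethodCall], final_iteration: int,
                      methods: tuple[str, ...] = ALL_METHODS) -> VoteMatrix:
    """Votes from the final iteration's significant/confirmed calls.

    Covariate calls never enter the matrix (they are reported separately).
    """
    voted: dict[str, np.ndarray] = {}
    col = {m: i for i, m in enumerate(methods)}
    for call in calls:
        if call.iteration_index != final_iteration or call.is_covariate:
            continue
        if call.method not in col or not call.significant:
            continue
        row = voted.setdefault(call.snp_id, np.zeros(len(methods), dtype=bool))
        row[col[call.method]] = True
    snp_ids = list(voted)
    votes = (np.array([voted[s] for s in snp_ids])
             if snp_ids else np.zeros((0, len(methods)), dtype=bool))
    return VoteMatrix(snp_ids=snp_ids, methods=tuple(methods), votes=votes)


def consensus_select(votes: VoteMatrix,
                     min_methods: int = DEFAULT_MIN_METHODS) -> list[str]:
    """SNPs flagged by at least ``min_methods`` methods, input order kept."""
    if not 1 <= min_methods <= len(votes.methods):
        raise ValueError(
            f"min_methods must be in 1..{len(votes.methods)}")
    keep = votes.votes.sum(axis=1) >= min_methods
    return [s for s, k in zip(votes.snp_ids, keep) if k]


def count_frequency(calls: list[MethodCall],
                    methods: tuple[str, ...] = ALL_METHODS
                    ) -> list[FrequencyRecord]:
    """Per-SNP count of (method, iteration) pairs with a positive call.

    A method contributes at most one appearance per iteration; SNPs with
    zero appearances are absent from the output.
    """
    seen: dict[str, set[tuple[str, int]]] = {}
    order: list[str] = []
    for call in calls:
        if not call.significant or call.is_covariate or call.method not in methods:
            continue
        if call.snp_id not in seen:
            seen[call.snp_id] = set()
            order.append(call.snp_id)
        seen[call.snp_id].add((call.method, call.iteration_index))
    records = []
    for snp in order:
        pairs = seen[snp]
        by_it: dict[int, int] = {}
        for _, it in pairs:
            by_it[it] = by_it.get(it, 0) + 1
        records.append(FrequencyRecord(snp_id=snp, count=len(pairs),
                                       by_iteration=dict(sorted(by_it.items()))))
    return records


def confidence(count: int, n_methods: int, n_iterations: int,
               threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
               snp_id: str = "") -> ConfidenceScore:
    """Confidence = appearance count / (methods x iterations), in [0, 1].

    Scores strictly above ``threshold`` (default 0.5) mark the SNP as a
    likely true positive.
    """
    total = n_methods * n_iterations
    if total <= 0:
        raise ValueError("n_methods and n_iterations must be positive")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    score = count / total
    return ConfidenceScore(snp_id=snp_id, score=score,
                           is_true_positive_candidate=score > threshold)


def summarise(calls: list[MethodCall], iteration_records: list,
              phenotype: str, n_methods: int = len(ALL_METHODS),
              min_methods: int = DEFAULT_MIN_METHODS,
              threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
              config: dict | None = None) -> ConsensusReport:
    """Assemble the full report from all iterations' calls."""
    n_iterations = len(iteration_records)
    final_it = iteration_records[-1].iteration_index if iteration_records else 1
    votes = build_vote_matrix(calls, final_it)
    key = consensus_select(votes, min_methods)
    freqs = count_frequency(calls)
    confs = [confidence(f.count, n_methods, n_iterations,
                        threshold=threshold, snp_id=f.snp_id)
             for f in freqs]
    return ConsensusReport(
        phenotype=phenotype,
        iteration_records=iteration_records,
        calls=[c for c in calls if not c.is_covariate],
        votes=votes,
        key_snps=key,
        frequencies=freqs,
        confidences=confs,
        n_methods=n_methods,
        n_iterations=n_iterations,
        covariate_calls=[c for c in calls if c.is_covariate],
        config=dict(config or {}),
    )
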