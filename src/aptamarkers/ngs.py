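"""FASTQ random-region extraction, frequency counting and candidate selection.

Selection libraries consist of reads built as
``5' flank + 40-mer random region + 3' flank``.  Extraction accepts a read
iff both constant flanks match at their fixed positions (each within a
configurable number of substitutions) and returns the intervening 40-mer.
Per-sample unique-sequence counts become relative frequencies against the
per-sample extracted total; the top-N sequences by summed copy number feed
a sparse PLS-DA that picks candidate aptamers discriminating the two
amyloid classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .features import FeatureStandardizer
from .simulate import FLANK3, FLANK5
from .splsda import DEFAULT_KEEPX_GRID, SparsePLSDA
from .prediction import classify, evaluate

__all__ = [
    "ExtractionReport",
    "AptamerCountMatrix",
    "SelectionResult",
    "extract_random_regions",
    "count_frequencies",
    "top_n_matrix",
    "select_candidate_aptamers",
]

REGION_LENGTH = 40
_VALID = set("ACGT")


@dataclass(frozen=True)
class ExtractionReport:
    """Partition of all reads in one FASTQ: extracted + rejected = total."""

    n_reads: int
    n_extracted: int
    n_rejected_flank: int
    n_rejected_length: int

    def __post_init__(self):
        if self.n_reads != (
            self.n_extracted + self.n_rejected_flank + self.n_rejected_length
        ):
            raise ValueError("extraction report does not partition the reads")


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def extract_random_regions(
    fastq: str | Path,
    flank5: str = FLANK5,
    flank3: str = FLANK3,
    max_mismatch: int = 0,
    region_length: int = REGION_LENGTH,
) -> tuple[list[str], ExtractionReport]:
    """Pull the 40-mer random regions out of one FASTQ library.

    A read is accepted iff it is long enough to hold
    ``flank5 + region + flank3``, ``flank5`` matches at the 5' end and
    ``flank3`` at position ``len(flank5) + region_length``, each within
    ``max_mismatch`` substitutions, and the region is pure A/C/G/T.  Too
    short reads count as length rejections; all other failures count as
    flank rejections.  The report always partitions the input.
    """
    if not flank5 or not flank3:
        raise ValueError("flanks must be non-empty DNA strings")
    flank5, flank3 = flank5.upper(), flank3.upper()
    need = len(flank5) + region_length + len(flank3)
    extracted: list[str] = []
    n_reads = n_flank = n_length = 0
    try:
        with open(fastq) as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                n_reads += 1
                seq = seq.upper()
                if len(seq) < need:
                    n_length += 1
                    continue
                if _mismatches(seq[: len(flank5)], flank5) > max_mismatch:
                    n_flank += 1
                    continue
                start = len(flank5) + region_length
                if _mismatches(seq[start : start + len(flank3)], flank3) > max_mismatch:
                    n_flank += 1
                    continue
                region = seq[len(flank5) : start]
                if not set(region) <= _VALID:
                    n_flank += 1
                    continue
                extracted.append(region)
    except ValueError as exc:
        raise ValueError(
            f"malformed FASTQ record around read {n_reads + 1} in {fastq}: {exc}"
        ) from exc
    return extracted, ExtractionReport(
        n_reads=n_reads,
        n_extracted=len(extracted),
        n_rejected_flank=n_flank,
        n_rejected_length=n_length,
    )


@dataclass
class AptamerCountMatrix:
    """Sample x unique-sequence counts with per-sample extracted totals.

    ``rel_freq`` divides counts by the per-sample total of *extracted*
    reads, so later top-N truncation does not distort frequencies (rows sum
    to 1 only before truncation).
    """

    counts: pd.DataFrame  # samples x sequences, integer
    totals: pd.Series  # per-sample extracted reads

    def __post_init__(self):
        bad = [
            s
            for s in self.counts.columns
            if len(s) != REGION_LENGTH or not set(s) <= _VALID
        ]
        if bad:
            raise ValueError(
                f"sequences must be {REGION_LENGTH}-mers over ACGT; bad: {bad[:3]}"
            )
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sequences(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def rel_freq(self) -> pd.DataFrame:
        return self.counts.div(self.totals, axis=0)


def count_frequencies(extracted: dict[str, list[str]]) -> AptamerCountMatrix:
    """Unique-sequence count matrix from per-sample extracted 40-mer lists."""
    if not extracted:
        raise ValueError("no samples provided")
    empty = [sid for sid, seqs in extracted.items() if len(seqs) == 0]
    if empty:
        raise ValueError(f"sample(s) with zero extracted reads: {empty}")
    counters = {sid: Counter(seqs) for sid, seqs in extracted.items()}
    counts = (
        pd.DataFrame(counters)
        .T.fillna(0)
        .astype(int)
        .sort_index(axis=1)
        .loc[list(extracted)]
    )
    totals = pd.Series({sid: len(seqs) for sid, seqs in extracted.items()})
    return AptamerCountMatrix(counts=counts, totals=totals)


def top_n_matrix(m: AptamerCountMatrix, n: int) -> AptamerCountMatrix:
    """Retain the ``n`` sequences with the largest counts summed over samples.

    Ties are broken lexicographically by sequence.  Relative frequencies are
    *not* renormalized after truncation (totals keep the full extracted
    counts).  All sequences are kept when fewer than ``n`` exist.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sums = m.counts.sum(axis=0)
    order = sorted(m.counts.columns, key=lambda s: (-sums[s], s))
    keep = order[:n]
    return AptamerCountMatrix(counts=m.counts[keep], totals=m.totals)


@dataclass
class SelectionResult:
    """Candidate aptamers, their loadings, and achieved LOO CV metrics."""

    sequences: list[str]
    loadings: pd.Series
    keep_x: int
    loo_sensitivity: float
    loo_specificity: float
    loo_accuracy: float
    target_reached: bool

    def to_dict(self) -> dict:
        return {
            "sequences": list(self.sequences),
            "loadings": {s: float(self.loadings[s]) for s in self.sequences},
            "keep_x": self.keep_x,
            "loo_sensitivity": self.loo_sensitivity,
            "loo_specificity": self.loo_specificity,
            "loo_accuracy": self.loo_accuracy,
            "target_reached": self.target_reached,
        }


def _loo_metrics(X: pd.DataFrame, y: np.ndarray, keep_x: int):
    """Leave-one-out nearest-zero calls with per-fold standardization."""
    calls = []
    for i in range(len(y)):
        mask = np.ones(len(y), bool)
        mask[i] = False
        std = FeatureStandardizer().fit(X.iloc[mask])
        model = SparsePLSDA(
            n_components=1, keep_x=min(keep_x, len(std.features_))
        ).fit(std.transform(X.iloc[mask]), y[mask])
        score = model.decision_function(std.transform(X.iloc[[i]]))[0]
        calls.append(classify(score, model.class_stats_).call)
    return evaluate(calls, y)


def select_candidate_aptamers(
    m: AptamerCountMatrix,
    labels,
    target_perfect_cv: bool = False,
    keepx_grid=None,
    seed: int | None = None,
) -> SelectionResult:
    """Pick the sequences that discriminate the two classes by sPLS-DA.

    The relative frequencies are standardized and fit with a one-component
    sparse PLS-DA; the selected set is the nonzero-loading sequences ordered
    by |loading| descending.  With ``target_perfect_cv`` the sparsity keep_x
    is increased over the grid until leave-one-out sensitivity and
    specificity both reach 1.0 (or the grid is exhausted); otherwise the
    keep_x minimizing LOO misclassification is used.  Either way the
    achieved LOO metrics are reported — the selection step is known to be
    unstable across data realizations, so the result carries its own
    evidence rather than promising a fixed panel size.

    ``seed`` is accepted for interface stability; the procedure itself is
    deterministic, so run-to-run variation comes only from the input data.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError(
            f"need both classes among samples, got {np.unique(labels).tolist()}"
        )
    X = m.rel_freq
    p = X.shape[1]
    grid = sorted({min(k, p) for k in (keepx_grid or DEFAULT_KEEPX_GRID)} | {p})

    chosen = None
    best_cm = None
    if target_perfect_cv:
        for keep in grid:
            cm = _loo_metrics(X, labels, keep)
            chosen, best_cm = keep, cm
            if cm.sensitivity == 1.0 and cm.specificity == 1.0:
                break
    else:
        results = {k: _loo_metrics(X, labels, k) for k in grid}
        chosen = min(grid, key=lambda k: (1 - results[k].accuracy, k))
        best_cm = results[chosen]

    std = FeatureStandardizer().fit(X)
    model = SparsePLSDA(n_components=1, keep_x=min(chosen, len(std.features_))).fit(
        std.transform(X), labels
    )
    loadings = model.loadings_series(0)
    nonzero = loadings[loadings != 0]
    ordered = nonzero.reindex(nonzero.abs().sort_values(ascending=False).index)
    return SelectionResult(
        sequences=list(ordered.index),
        loadings=loadings,
        keep_x=chosen,
        loo_sensitivity=best_cm.sensitivity,
        loo_specificity=best_cm.specificity,
        loo_accuracy=best_cm.accuracy,
        target_reached=(best_cm.sensitivity == 1.0 and best_cm.specificity == 1.0),
    )
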