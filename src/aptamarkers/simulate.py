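"""Synthetic cohorts, qPCR amplification curves and selection-library reads.

The generators emulate the statistical structure of an aptamer ("Aptamarker")
screening study: a cohort of elderly, cognitively normal individuals labelled
amyloid-positive or -negative by a PET SUVR threshold; a panel of aptamers
quantified per sample by qPCR, a few of which carry a class-dependent Cq
shift; and per-sample post-selection sequencing libraries in which a handful
of 40-mer aptamer sequences are enriched in one class.

Every generator is driven by a single integer seed and is bit-reproducible:
the same :class:`SimulationConfig` always yields identical outputs, including
byte-identical FASTQ files.  Ground truth (true sigmoid midpoints, the list of
informative aptamers, the enriched sequences) is always returned alongside, so
downstream parameter-recovery tests can score themselves against it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FLANK5",
    "FLANK3",
    "SampleRecord",
    "SimulationConfig",
    "SelectionLibraries",
    "simulate_cohort",
    "simulate_amplification_curves",
    "simulate_selection_reads",
    "cohort_to_frame",
]

#: Constant 5' flank of the selection library (primer hybridization region).
FLANK5 = "AACTACATGGTATGTGGTGAACT"
#: Constant 3' flank of the selection library.
FLANK3 = "GACGTACAATGTACCCTATAGTG"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SampleRecord:
    """One cohort member.

    ``amyloid_class`` is ``"pos"`` iff ``suvr`` exceeds the class threshold
    (default 0.79); SUVR is the standardized uptake value ratio from amyloid
    PET, dimensionless and positive.
    """

    sample_id: str
    suvr: float
    amyloid_class: str
    age: float
    sex: str
    apoe: str


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the cohort the analysis is designed for: 69 usable
    samples (one of the 70 originals excluded as an outlier) with a 39/70
    positive fraction, a 44-aptamer qPCR panel read over 30 cycles, and
    22 selection libraries.  ``cq_shift`` is the between-class difference in
    true sigmoid midpoint (cycles) on the ``n_informative`` informative
    aptamers; ``cq_noise_sd`` is per-(sample, aptamer) Gaussian jitter on the
    midpoint.  ``enrichment_fold`` multiplies the sampling weight of each
    enriched 40-mer in positive-class libraries.
    """

    n_samples: int = 69
    pos_fraction: float = 39 / 70
    panel_size: int = 44
    n_informative: int = 5
    cq_shift: float = 2.0
    cq_noise_sd: float = 0.5
    n_cycles: int = 30
    reads_per_library: int = 10_000
    n_enriched_sequences: int = 3
    enrichment_fold: float = 10.0
    seed: int = 0
    class_threshold: float = 0.79
    # qPCR curve shape: F(c) = baseline + plateau / (1 + exp(-slope*(c - c0)))
    # + N(0, curve_noise_sd).  A logistic is the standard qPCR shape; the
    # default slope ln(2) corresponds to per-cycle doubling (efficiency 1).
    curve_baseline: float = 100.0
    curve_plateau: float = 1000.0
    curve_slope: float = 0.6931471805599453
    curve_noise_sd: float = 2.0
    background_pool_size: int = 200

    def __post_init__(self) -> None:
        if self.n_informative > self.panel_size:
            raise ValueError(
                f"n_informative ({self.n_informative}) exceeds panel_size "
                f"({self.panel_size})"
            )
        if self.n_enriched_sequences < 0:
            raise ValueError("n_enriched_sequences must be >= 0")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if not 0 < self.pos_fraction < 1:
            raise ValueError("pos_fraction must lie in (0, 1)")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


# Table-1-style cohort composition used for covariate sampling.
_AGE_MEAN = 77.4
_AGE_SD = {"neg": 3.1, "pos": 3.7}
_FEMALE_P = {"neg": 16 / 31, "pos": 21 / 39}
_APOE_LEVELS = ["E2/E3", "E3/E3", "E3/E4", "E4/E4"]
_APOE_P = {
    "neg": np.array([5, 22, 3, 1]) / 31,
    "pos": np.array([1, 20, 16, 2]) / 39,
}


def simulate_cohort(config: SimulationConfig) -> list[SampleRecord]:
    """Draw a cohort with class counts ``round(n * pos_fraction)`` positive.

    Negative-class SUVR ~ Uniform(0.60, 0.78), positive ~ Uniform(0.80, 1.20),
    so the class/threshold invariant holds by construction.  Age, sex and
    APOE genotype are sampled per class from the study composition; they are
    carried as metadata and never modelled downstream.
    """
    if config.n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    n = config.n_samples
    n_pos = round(n * config.pos_fraction)
    n_neg = n - n_pos
    if n_pos < 1 or n_neg < 1:
        raise ValueError(
            f"degenerate cohort: {n_neg} negative / {n_pos} positive samples; "
            "need at least one sample per class"
        )
    rng = np.random.default_rng(config.seed)
    classes = np.array(["neg"] * n_neg + ["pos"] * n_pos)
    classes = classes[rng.permutation(n)]
    width = len(str(n))
    records = []
    for i, cls in enumerate(classes):
        if cls == "pos":
            suvr = rng.uniform(0.80, 1.20)
        else:
            suvr = rng.uniform(0.60, 0.78)
        age = rng.normal(_AGE_MEAN, _AGE_SD[cls])
        sex = "F" if rng.random() < _FEMALE_P[cls] else "M"
        apoe = _APOE_LEVELS[rng.choice(4, p=_APOE_P[cls])]
        records.append(
            SampleRecord(
                sample_id=f"S{i + 1:0{width}d}",
                suvr=float(suvr),
                amyloid_class=cls,
                age=float(age),
                sex=sex,
                apoe=apoe,
            )
        )
    return records


def cohort_to_frame(samples: list[SampleRecord]) -> pd.DataFrame:
    """Cohort metadata as a DataFrame (one row per sample)."""
    return pd.DataFrame([dataclasses.asdict(s) for s in samples])


def _aptamer_ids(panel_size: int) -> list[str]:
    width = max(2, len(str(panel_size)))
    return [f"APT{i + 1:0{width}d}" for i in range(panel_size)]


def simulate_amplification_curves(
    samples: list[SampleRecord], config: SimulationConfig
) -> tuple[pd.DataFrame, dict]:
    """Simulate one logistic amplification curve per (sample, aptamer).

    Returns a long-format DataFrame with columns ``sample_id, aptamer_id,
    cycle, fluorescence`` (cycles 1..n_cycles) and a ground-truth dict with
    the informative aptamer ids and the true midpoint of every curve.

    The first ``n_informative`` panel members are informative: their true
    midpoint differs between classes by ``cq_shift`` cycles (direction
    alternating across aptamers), on top of per-curve Gaussian jitter
    ``cq_noise_sd``.  All other aptamers are class-independent.
    """
    if config.panel_size < 1:
        raise ValueError("panel_size must be >= 1")
    if config.n_cycles < 12:
        raise ValueError(
            f"n_cycles={config.n_cycles} < 12: the baseline window "
            "(cycles 3-10) must fit inside the run"
        )
    rng = np.random.default_rng(config.seed)
    aptamers = _aptamer_ids(config.panel_size)
    # midpoints late enough that cycles 3-10 are genuinely baseline (the
    # assumption the derivative-threshold Cq caller makes of real curves)
    base_mid = rng.uniform(19.0, 24.0, size=config.panel_size)
    informative = aptamers[: config.n_informative]
    # alternate shift direction so informative signal is not one-sided
    sign = np.array([1 if i % 2 == 0 else -1 for i in range(config.n_informative)])

    cycles = np.arange(1, config.n_cycles + 1)
    rows = []
    truth_rows = []
    for s in samples:
        for j, apt in enumerate(aptamers):
            mid = base_mid[j]
            if j < config.n_informative:
                delta = sign[j] * config.cq_shift / 2.0
                mid = mid + (delta if s.amyloid_class == "pos" else -delta)
            mid = mid + rng.normal(0.0, config.cq_noise_sd) if config.cq_noise_sd > 0 else mid
            fluor = config.curve_baseline + config.curve_plateau / (
                1.0 + np.exp(-config.curve_slope * (cycles - mid))
            )
            if config.curve_noise_sd > 0:
                fluor = fluor + rng.normal(0.0, config.curve_noise_sd, config.n_cycles)
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": s.sample_id,
                        "aptamer_id": apt,
                        "cycle": cycles,
                        "fluorescence": fluor,
                    }
                )
            )
            truth_rows.append((s.sample_id, apt, float(mid)))
    curves = pd.concat(rows, ignore_index=True)
    truth = {
        "informative_aptamers": informative,
        "aptamer_base_midpoint": dict(zip(aptamers, base_mid.tolist())),
        "true_midpoints": pd.DataFrame(
            truth_rows, columns=["sample_id", "aptamer_id", "true_midpoint"]
        ),
    }
    return curves, truth


@dataclass
class SelectionLibraries:
    """Result of :func:`simulate_selection_reads`."""

    fastq_paths: dict[str, Path]
    enriched_sequences: list[str]
    background_sequences: list[str] = field(repr=False, default_factory=list)

    def write_ground_truth(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"enriched_sequences": self.enriched_sequences}, indent=2)
        )


def _random_kmers(rng: np.random.Generator, n: int, length: int = 40) -> list[str]:
    """``n`` distinct random DNA ``length``-mers."""
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        draw = _BASES[rng.integers(0, 4, size=(n - len(seqs), length))]
        for row in draw:
            s = "".join(row)
            if s not in seen:
                seen.add(s)
                seqs.append(s)
    return seqs


def simulate_selection_reads(
    samples: list[SampleRecord],
    config: SimulationConfig,
    out_dir: str | Path,
) -> SelectionLibraries:
    """Write one FASTQ selection library per sample.

    Every read is ``FLANK5 + 40-mer + FLANK3`` (86 nt) with constant quality
    'I'.  A shared background pool of ``background_pool_size`` 40-mers is
    sampled uniformly; ``n_enriched_sequences`` additional 40-mers carry
    ``enrichment_fold``-times-higher sampling weight in positive-class
    libraries.  The enriched-sequence list is returned (and can be written as
    a JSON sidecar) as ground truth.
    """
    if config.reads_per_library <= 0:
        raise ValueError("reads_per_library must be > 0")
    present = {s.amyloid_class for s in samples}
    if present != {"neg", "pos"}:
        raise ValueError(
            f"selection libraries need both classes present, got {sorted(present)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    pool = _random_kmers(
        rng, config.background_pool_size + config.n_enriched_sequences
    )
    background = pool[: config.background_pool_size]
    enriched = pool[config.background_pool_size :]
    all_seqs = np.array(background + enriched)
    w_neg = np.ones(len(all_seqs))
    w_pos = np.ones(len(all_seqs))
    w_pos[config.background_pool_size :] = config.enrichment_fold
    p_class = {"neg": w_neg / w_neg.sum(), "pos": w_pos / w_pos.sum()}

    paths: dict[str, Path] = {}
    qual = "I" * (len(FLANK5) + 40 + len(FLANK3))
    for s in samples:
        counts = rng.multinomial(config.reads_per_library, p_class[s.amyloid_class])
        reads = np.repeat(all_seqs, counts)
        reads = reads[rng.permutation(len(reads))]
        path = out_dir / f"{s.sample_id}.fastq"
        with open(path, "w") as fh:
            for i, kmer in enumerate(reads):
                fh.write(f"@{s.sample_id}_read{i + 1}\n{FLANK5}{kmer}{FLANK3}\n+\n{qual}\n")
        paths[s.sample_id] = path
    return SelectionLibraries(
        fastq_paths=paths,
        enriched_sequences=list(enriched),
        background_sequences=list(background),
    )
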