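"""Self-contained recovery experiments on fully synthetic studies.

These workflows exercise the whole pipeline against the generator's ground
truth: can repeated hold-out cross-validation recover near-perfect
classification when a handful of panel aptamers truly carry a class Cq
shift, and does the NGS selection stage recover the truly enriched
sequences?  They are used both by the test suite and by the results
reproduction script.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

from .features import build_features, cq_long_to_wide, fit_standardizer
from .ngs import count_frequencies, extract_random_regions, select_candidate_aptamers
from .prediction import cross_validate
from .qpcr import call_cq_table
from .simulate import (
    SimulationConfig,
    cohort_to_frame,
    simulate_amplification_curves,
    simulate_cohort,
    simulate_selection_reads,
)
from .splsda import SparsePLSDA

__all__ = ["cq_shift_recovery", "enrichment_recovery"]


def cq_shift_recovery(
    seed: int,
    config: SimulationConfig | None = None,
    n_repeats: int = 5,
    n_train: int = 54,
    n_test: int = 15,
    top_k: int = 10,
) -> dict:
    """Full curves -> Cq -> features -> CV chain on one synthetic study.

    Simulates the default study (69 samples, 44 aptamers, 5 informative with
    a 2-cycle class shift and 0.5-cycle noise), runs repeated 54/15 hold-out
    cross-validation, and checks whether every informative aptamer appears
    (as a raw Cq or inside a ratio) among the ``top_k`` largest |loading|
    features of a full-cohort fit.
    """
    cfg = (config or SimulationConfig()).replace(seed=seed)
    cohort = simulate_cohort(cfg)
    curves, truth = simulate_amplification_curves(cohort, cfg)
    cq = call_cq_table(curves, with_efficiency=False)
    fm = build_features(cq_long_to_wide(cq))
    labels = (
        cohort_to_frame(cohort)
        .set_index("sample_id")["amyloid_class"]
        .reindex(fm.index)
        .to_numpy()
    )
    report = cross_validate(
        fm, labels, n_repeats=n_repeats, n_train=n_train, n_test=n_test, seed=seed
    )

    Z, _ = fit_standardizer(fm)
    model = SparsePLSDA(n_components=1).fit(Z, labels)
    loadings = model.loadings_series(0)
    top = loadings.abs().sort_values(ascending=False).head(top_k).index
    mentioned = {apt for name in top for apt in str(name).split("/")}
    informative = set(truth["informative_aptamers"])
    return {
        "mean_cv_accuracy": report.mean_accuracy,
        "mean_cv_sensitivity": report.mean_sensitivity,
        "mean_cv_specificity": report.mean_specificity,
        "informative_in_top": informative <= mentioned,
        "n_informative_in_top": len(informative & mentioned),
        "top_features": list(map(str, top)),
    }


def enrichment_recovery(
    seed: int,
    config: SimulationConfig | None = None,
    n_libraries: int = 22,
    out_dir: str | Path | None = None,
) -> dict:
    """Simulated selection libraries -> extraction -> counting -> selection.

    Builds 11 + 11 class-balanced FASTQ libraries with 3 sequences enriched
    10-fold among a 200-sequence background, and checks that candidate
    selection recovers all enriched sequences and that the extraction report
    conserves read counts on every library.
    """
    cfg = (config or SimulationConfig()).replace(seed=seed)
    cohort = simulate_cohort(cfg)
    half = n_libraries // 2
    neg = [s for s in cohort if s.amyloid_class == "neg"][:half]
    pos = [s for s in cohort if s.amyloid_class == "pos"][: n_libraries - half]

    def _run(workdir):
        libs = simulate_selection_reads(neg + pos, cfg, workdir)
        extracted = {}
        conserved = True
        for sid, path in libs.fastq_paths.items():
            seqs, rep = extract_random_regions(path)
            conserved &= rep.n_reads == (
                rep.n_extracted + rep.n_rejected_flank + rep.n_rejected_length
            )
            extracted[sid] = seqs
        matrix = count_frequencies(extracted)
        labels = [s.amyloid_class for s in neg + pos]
        sel = select_candidate_aptamers(matrix, labels, target_perfect_cv=True)
        enriched = set(libs.enriched_sequences)
        return {
            "all_enriched_selected": enriched <= set(sel.sequences),
            "enriched_in_top5": enriched <= set(sel.sequences[:5]),
            "n_selected": len(sel.sequences),
            "reports_conserve_reads": conserved,
            "loo_sensitivity": sel.loo_sensitivity,
            "loo_specificity": sel.loo_specificity,
        }

    if out_dir is not None:
        return _run(Path(out_dir))
    with tempfile.TemporaryDirectory() as td:
        return _run(Path(td))
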