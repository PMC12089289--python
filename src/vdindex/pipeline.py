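"""End-to-end orchestration: counts + participants in, report + tables out.

Every number in the run report is recomputed from the persisted
intermediate tables; re-running with the same inputs and seed produces
byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    build_index,
    index_correlations,
    serum_summary,
    stability_analysis,
)
from .expression import (
    DETable,
    cpm,
    filter_genes,
    mds_embed,
    paired_de,
    participant_log2fc,
    tmm_factors,
)
from .io import (
    CohortTable,
    CohortValidationError,
    CountMatrix,
    GeneAnnotation,
    write_table,
)

log = logging.getLogger("vdindex")


@dataclass
class RunConfig:
    """Thresholds and flags of one pipeline run."""

    cpm_min: float = 10.0
    p_sig: float = 0.05
    tau: float = 0.25
    fdr_sig: float = 0.05
    k: int = 3
    prior_cpm: float = 0.5
    zscore_axes: bool = False
    per_timepoint_harmonization: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("cpm_min", "p_sig", "tau", "fdr_sig", "prior_cpm"):
            if getattr(self, name) < 0:
                raise CohortValidationError(f"{name} must be non-negative")
        if self.k < 2:
            raise CohortValidationError("k must be at least 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    de: pd.DataFrame
    fc_values: pd.DataFrame
    index: pd.DataFrame
    stability: pd.DataFrame
    serum: dict
    report: dict
    artifacts: dict[str, Path] = field(default_factory=dict)


def run_pipeline(
    counts: CountMatrix,
    cohort: CohortTable,
    annotation: GeneAnnotation,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run normalization, DE, index construction and stability analysis.

    When ``outdir`` is given, all intermediate tables (cpm, de, fc, index,
    stability, mds) plus a machine-readable report and the effective config
    are persisted there as TSV/JSON.
    """
    config = config or RunConfig()
    log.info("stage serum: %d participants", len(cohort))
    serum = serum_summary(cohort)

    log.info("stage normalize: %d genes x %d samples",
             len(counts.gene_ids), len(counts.sample_ids))
    raw_cpm = cpm(counts)
    mask = filter_genes(raw_cpm, annotation, threshold=config.cpm_min)
    kept = list(mask.index[mask])
    if not kept:
        raise CohortValidationError("no genes pass the expression filter")
    filtered = CountMatrix(
        counts=counts.counts.loc[kept], sample_map=counts.sample_map
    )
    factors = tmm_factors(filtered)
    norm_cpm = cpm(filtered, norm_factors=factors)

    log.info("stage de: %d expressed genes", len(kept))
    de = paired_de(norm_cpm, tau=config.tau, prior=config.prior_cpm,
                   alpha=config.p_sig, fdr_alpha=config.fdr_sig)
    sets = DETable.significant_sets(de)
    fc = participant_log2fc(norm_cpm, prior=config.prior_cpm)

    ratios = pd.Series(
        {r.participant_id: r.serum_ratio for r in cohort.records}, name="serum_ratio"
    ).loc[fc.participant_ids]

    log.info("stage classify: %d significant genes", len(sets["p05"]))
    if not sets["p05"]:
        raise CohortValidationError("no significant genes: cannot build index")
    index = build_index(fc, sets["p05"], ratios, gene_set_label="p05",
                        k=config.k, zscore_axes=config.zscore_axes)
    stability = stability_analysis(fc, de, ratios, k=config.k)

    dist = index.set_index("participant_id")["distance"]
    covars = {
        "serum_ratio": np.array([r.serum_ratio for r in cohort.records]),
        "baseline_serum": np.array([r.serum_d0 for r in cohort.records]),
        "age": np.array([float(r.age) for r in cohort.records]),
        "bmi": np.array([r.bmi for r in cohort.records]),
    }
    d_arr = dist.loc[[r.participant_id for r in cohort.records]].to_numpy()
    correlations = {
        name: dict(zip(("r", "p"), index_correlations(d_arr, v)))
        for name, v in covars.items()
    }

    mds = mds_embed(norm_cpm, sorted(sets["p05"]), k=2, prior=config.prior_cpm)

    class_sizes = index["class"].value_counts().to_dict()
    report = {
        "version": __version__,
        "config": config.to_dict(),
        "serum": dataclasses.asdict(serum),
        "de_summary": {
            "n_expressed": len(kept),
            "n_sig_p05": len(sets["p05"]),
            "n_sig_p05_up": int((de["sig_p05"] & (de["direction"] == "up")).sum()),
            "n_sig_p05_down": int((de["sig_p05"] & (de["direction"] == "down")).sum()),
            "n_sig_lfc": len(sets["lfc"]),
            "n_sig_fdr": len(sets["fdr"]),
        },
        "classification": {
            "class_sizes": {c: int(class_sizes.get(c, 0))
                            for c in ("high", "mid", "low")},
            "correlations": correlations,
        },
        "stability": {
            "n_stable": int(stability["stable"].sum()),
            "n_unstable": int((~stability["stable"]).sum()),
            "unstable": sorted(
                stability.loc[~stability["stable"], "participant_id"].astype(str)
            ),
        },
    }

    artifacts: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        artifacts["cpm"] = write_table(
            norm_cpm.values.rename_axis("gene_id").reset_index(), outdir / "cpm.tsv"
        )
        artifacts["de"] = write_table(de, outdir / "de.tsv")
        artifacts["fc"] = write_table(
            fc.values.rename_axis("participant_id").reset_index(), outdir / "fc.tsv"
        )
        artifacts["index"] = write_table(index, outdir / "index.tsv")
        artifacts["stability"] = write_table(stability, outdir / "stability.tsv")
        mds_df = pd.DataFrame(
            mds.coordinates, columns=["dim1", "dim2"], index=mds.sample_ids
        ).rename_axis("sample_id").reset_index()
        artifacts["mds"] = write_table(mds_df, outdir / "mds.tsv")
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        (outdir / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        artifacts["report"] = outdir / "report.json"

    return PipelineResult(
        de=de,
        fc_values=fc.values,
        index=index,
        stability=stability,
        serum=dataclasses.asdict(serum),
        report=report,
        artifacts=artifacts,
    )
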