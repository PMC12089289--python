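"""Two-cohort merging: shared genes, expression harmonization, joint classes.

Two independently sequenced cohorts are merged on their common gene ids and
brought to a shared expression scale by per-gene mean-ratio scaling: each
cohort's CPM for a gene is multiplied by (grand mean across both cohorts) /
(cohort mean), so post-harmonization per-gene cohort means agree. Because
the factor is constant within a cohort and gene, it cancels in every
within-participant d1/d0 ratio — harmonization never alters fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import build_index
from .expression import CPMMatrix, DETable, FoldChangeMatrix, participant_log2fc
from .io import CohortValidationError

__all__ = ["MergedCohort", "OverlapResult", "intersect_targets", "harmonize",
           "joint_classify"]


@dataclass
class OverlapResult:
    """Intersection of two DE target-gene sets with direction concordance."""

    size_a: int
    size_b: int
    size_intersection: int
    n_up_up: int
    n_down_down: int
    n_discordant: int

    @property
    def n_concordant(self) -> int:
        return self.n_up_up + self.n_down_down


@dataclass
class MergedCohort:
    """Harmonized per-cohort CPM matrices restricted to shared genes."""

    cohorts: dict[str, CPMMatrix]
    scaling_factors: pd.DataFrame  # genes x cohorts
    common_gene_ids: list[str]


def intersect_targets(de_a: pd.DataFrame, de_b: pd.DataFrame,
                      flag: str = "sig_p05") -> OverlapResult:
    """Overlap of genes passing ``flag`` in each table, split by direction."""
    DETable.validate(de_a)
    DETable.validate(de_b)
    if flag not in ("sig_p05", "sig_lfc", "sig_fdr"):
        raise CohortValidationError(f"unknown significance flag {flag!r}")
    a = de_a.loc[de_a[flag]].set_index("gene_id")
    b = de_b.loc[de_b[flag]].set_index("gene_id")
    common = a.index.intersection(b.index)
    da = np.sign(a.loc[common, "log2fc"].to_numpy())
    db = np.sign(b.loc[common, "log2fc"].to_numpy())
    up_up = int(np.sum((da > 0) & (db > 0)))
    dn_dn = int(np.sum((da < 0) & (db < 0)))
    return OverlapResult(
        size_a=len(a),
        size_b=len(b),
        size_intersection=len(common),
        n_up_up=up_up,
        n_down_down=dn_dn,
        n_discordant=len(common) - up_up - dn_dn,
    )


def harmonize(cpm_by_cohort: dict[str, CPMMatrix],
              per_timepoint: bool = False) -> MergedCohort:
    """Merge cohorts on common genes and equalize per-gene mean expression.

    ``per_timepoint=True`` computes separate factors for d0 and d1 samples
    (equalizing timepoint means instead of cohort means); this variant
    distorts within-participant fold changes and is off by default.
    """
    if len(cpm_by_cohort) < 2:
        raise CohortValidationError("need at least two cohorts to merge")
    gene_sets = [set(c.gene_ids) for c in cpm_by_cohort.values()]
    common = set.intersection(*gene_sets)
    if not common:
        raise CohortValidationError("no common genes across cohorts")
    first = next(iter(cpm_by_cohort.values()))
    common_ids = [g for g in first.gene_ids if g in common]

    sub = {name: c.values.loc[common_ids] for name, c in cpm_by_cohort.items()}
    all_values = pd.concat(list(sub.values()), axis=1)
    grand_mean = all_values.mean(axis=1)
    cohort_means = pd.DataFrame({name: v.mean(axis=1) for name, v in sub.items()})
    zero = (cohort_means <= 0).any(axis=1) | (grand_mean <= 0)
    if zero.any():
        dropped = list(cohort_means.index[zero])
        warnings.warn(
            f"dropping {len(dropped)} genes with zero mean in some cohort",
            stacklevel=2,
        )
        common_ids = [g for g in common_ids if g not in set(dropped)]
        sub = {name: v.loc[common_ids] for name, v in sub.items()}
        grand_mean = grand_mean.loc[common_ids]
        cohort_means = cohort_means.loc[common_ids]

    factors = pd.DataFrame(index=pd.Index(common_ids, name="gene_id"))
    harmonized: dict[str, CPMMatrix] = {}
    for name, values in sub.items():
        src = cpm_by_cohort[name]
        if per_timepoint:
            scaled = values.copy()
            for tp in ("d0", "d1"):
                cols = [s for s in values.columns
                        if src.sample_map.loc[s, "timepoint"] == tp]
                tp_mean = values[cols].mean(axis=1)
                f = grand_mean / tp_mean.replace(0.0, np.nan)
                scaled[cols] = values[cols].mul(f.fillna(1.0), axis=0)
            factors[name] = grand_mean / cohort_means[name]
        else:
            f = grand_mean / cohort_means[name]
            scaled = values.mul(f, axis=0)
            factors[name] = f
        harmonized[name] = CPMMatrix(
            values=scaled, norm_factors=src.norm_factors, sample_map=src.sample_map
        )
    return MergedCohort(
        cohorts=harmonized, scaling_factors=factors, common_gene_ids=common_ids
    )


def joint_classify(
    merged: MergedCohort,
    common_targets,
    serum_ratios: dict[str, pd.Series],
    single_classes: dict[str, pd.DataFrame] | None = None,
    prior: float = 0.5,
    k: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pool all participants and classify them on the common target set.

    Participant ids are prefixed ``<cohort>:`` to stay unique. When
    per-cohort ``single_classes`` index tables are given, a reclassification
    table comparing each participant's joint class with the single-cohort
    class is returned as well.
    """
    targets = [g for g in merged.common_gene_ids if g in set(common_targets)]
    if not targets:
        raise CohortValidationError("empty common target set")
    fc_frames = []
    ratio_parts = []
    provenance = {}
    for name, cpm_matrix in merged.cohorts.items():
        # offset rescaled per gene so harmonization cancels in the ratio
        gene_prior = prior * merged.scaling_factors[name].loc[targets]
        fc = participant_log2fc(cpm_matrix.subset_genes(targets), prior=gene_prior)
        frame = fc.values.copy()
        frame.index = [f"{name}:{pid}" for pid in frame.index]
        fc_frames.append(frame)
        ratios = serum_ratios[name]
        ratio_parts.append(
            pd.Series(ratios.to_numpy(dtype=float),
                      index=[f"{name}:{pid}" for pid in ratios.index])
        )
        for pid in ratios.index:
            provenance[f"{name}:{pid}"] = name
    joint_fc = FoldChangeMatrix(values=pd.concat(fc_frames, axis=0), prior=prior)
    joint_ratio = pd.concat(ratio_parts)
    joint = build_index(joint_fc, targets, joint_ratio,
                        gene_set_label="joint-common", k=k)
    joint["cohort"] = [provenance[p] for p in joint["participant_id"]]

    recls = None
    if single_classes is not None:
        rows = []
        for name, table in single_classes.items():
            single = dict(zip(table["participant_id"].astype(str), table["class"]))
            for pid, cls in single.items():
                jid = f"{name}:{pid}"
                jcls = joint.loc[joint["participant_id"] == jid, "class"]
                if jcls.empty:
                    continue
                rows.append(
                    {
                        "participant_id": pid,
                        "cohort": name,
                        "single_class": cls,
                        "joint_class": jcls.iloc[0],
                        "changed": cls != jcls.iloc[0],
                    }
                )
        recls = pd.DataFrame(rows)
    return joint, recls
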