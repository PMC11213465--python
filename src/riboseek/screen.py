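"""Tissue-specificity screen for lncRNA candidates.

Implements the nomination funnel: a gene is called tissue-specific when its
expression in every target-tissue sample exceeds a fold multiple of its
expression in any other sample, and candidates are then carried through
annotation, ortholog-mapping and cross-species specificity filters.

The specificity rule is deliberately the strictest reading of "X times
greater than in any of the other samples": the MINIMUM over target-tissue
samples is compared against the MAXIMUM over all remaining samples.  An
absolute expression floor (FPKM) guards against 0/0 and noise-only calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SpecificityCall",
    "OrthologMap",
    "FunnelStage",
    "FunnelReport",
    "compute_specificity",
    "filter_annotation",
    "map_orthologs",
    "cross_species_validate",
    "build_funnel_report",
    "run_screen",
]


@dataclass
class ExpressionMatrix:
    """FPKM expression values (genes x samples) with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene_id with one column per sample_id; entries
        are FPKM and must be non-negative.
    sample_meta
        DataFrame indexed by sample_id with columns ``species``, ``tissue``
        and ``replicate``; must cover every sample exactly once.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.size and (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative FPKM")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if self.sample_meta.index.has_duplicates:
            raise ValueError("duplicate sample_id in metadata")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def tissues(self) -> list[str]:
        return sorted(self.sample_meta["tissue"].unique())

    def samples_for_tissue(self, tissue: str) -> list[str]:
        hit = self.sample_meta.index[self.sample_meta["tissue"] == tissue]
        return [s for s in self.values.columns if s in set(hit)]

    @classmethod
    def from_tsv(cls, expr_path, meta_path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values, meta)

    def to_tsv(self, expr_path, meta_path) -> None:
        self.values.to_csv(expr_path, sep="\t", index_label="gene_id")
        self.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


@dataclass(frozen=True)
class SpecificityCall:
    """Outcome of the fold-specificity rule for one gene."""

    gene_id: str
    target_min: float
    other_max: float
    ratio: float | None  # undefined (None) when other_max == 0
    passes_floor: bool
    passes_fold: bool


@dataclass
class OrthologMap:
    """Cross-species gene pairs (gene_id_species_a, gene_id_species_b)."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate ortholog pairs")
        self._by_a: dict[str, list[str]] = {}
        for a, b in self.pairs:
            self._by_a.setdefault(a, []).append(b)

    def partners(self, gene_id: str) -> list[str]:
        return list(self._by_a.get(gene_id, []))

    @classmethod
    def from_tsv(cls, path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        return cls([tuple(r) for r in df.iloc[:, :2].itertuples(index=False)])


def compute_specificity(
    expr: ExpressionMatrix,
    target_tissue: str,
    fold: float = 5.0,
    floor: float = 0.5,
) -> list[SpecificityCall]:
    """Apply the min-over-target vs max-over-other fold rule to every gene.

    A gene passes when target_min >= floor and either other_max == 0
    (infinite specificity) or target_min / other_max >= fold.  The fold
    boundary is inclusive.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if floor < 0:
        raise ValueError("floor must be >= 0")
    if expr.values.empty:
        raise ValueError("empty expression matrix")
    target_samples = expr.samples_for_tissue(target_tissue)
    if not target_samples:
        raise KeyError(f"unknown target tissue: {target_tissue!r}")
    other_samples = [s for s in expr.sample_ids if s not in set(target_samples)]
    if not other_samples:
        raise ValueError("no non-target samples in matrix")

    tmin = expr.values[target_samples].min(axis=1).to_numpy(float)
    omax = expr.values[other_samples].max(axis=1).to_numpy(float)
    calls = []
    for gid, t, o in zip(expr.gene_ids, tmin, omax):
        ratio = (t / o) if o > 0 else None
        passes_floor = t >= floor
        passes_fold = passes_floor and (o == 0 or t / o >= fold)
        calls.append(SpecificityCall(gid, t, o, ratio, passes_floor, passes_fold))
    return calls


def filter_annotation(
    candidates: list[str], annotation: set[str]
) -> tuple[list[str], list[str]]:
    """Partition candidates into (retained, excluded) by annotation membership."""
    annotation = set(annotation)
    retained = [c for c in candidates if c in annotation]
    excluded = [c for c in candidates if c not in annotation]
    return retained, excluded


def map_orthologs(
    candidates: list[str], omap: OrthologMap
) -> tuple[dict[str, list[str]], list[str]]:
    """Partition candidates into mapped (with all partner ids) and unmapped."""
    mapped: dict[str, list[str]] = {}
    unmapped: list[str] = []
    for c in candidates:
        partners = omap.partners(c)
        if partners:
            mapped[c] = partners
        else:
            unmapped.append(c)
    return mapped, unmapped


def cross_species_validate(
    mapped: dict[str, list[str]],
    expr_b: ExpressionMatrix,
    target_tissue: str,
    fold: float = 5.0,
    floor: float = 0.5,
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Validate mapped candidates by partner specificity in the second species.

    A candidate validates when ANY of its partners passes the same fold/floor
    rule in ``expr_b``.  Partners absent from the matrix are treated as
    failing with reason "absent".
    """
    calls = {
        c.gene_id: c for c in compute_specificity(expr_b, target_tissue, fold, floor)
    }
    validated: dict[str, list[str]] = {}
    rejected: dict[str, str] = {}
    for cand, partners in mapped.items():
        good = [p for p in partners if p in calls and calls[p].passes_fold]
        if good:
            validated[cand] = good
        else:
            absent = [p for p in partners if p not in calls]
            rejected[cand] = (
                "absent" if len(absent) == len(partners) else "not_specific"
            )
    return validated, rejected


@dataclass(frozen=True)
class FunnelStage:
    name: str
    n_in: int
    n_excluded: int
    n_out: int
    excluded_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_out != self.n_in - self.n_excluded:
            raise ValueError(
                f"stage {self.name!r}: n_out {self.n_out} != "
                f"n_in {self.n_in} - n_excluded {self.n_excluded}"
            )


@dataclass
class FunnelReport:
    """Ordered, telescoping record of the screening funnel."""

    stages: list[FunnelStage] = field(default_factory=list)

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if nxt.n_in != prev.n_out:
                raise ValueError(
                    f"funnel chain broken: stage {nxt.name!r} n_in {nxt.n_in} "
                    f"!= previous n_out {prev.n_out}"
                )

    @property
    def n_initial(self) -> int:
        return self.stages[0].n_in if self.stages else 0

    @property
    def n_final(self) -> int:
        return self.stages[-1].n_out if self.stages else 0

    def stage(self, name: str) -> FunnelStage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "n_in": s.n_in,
                    "n_excluded": s.n_excluded,
                    "n_out": s.n_out,
                    "excluded_ids": list(s.excluded_ids),
                }
                for s in self.stages
            ],
            "n_initial": self.n_initial,
            "n_final": self.n_final,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def build_funnel_report(
    stages: list[tuple[str, list[str], list[str]]]
) -> FunnelReport:
    """Assemble a FunnelReport from ordered (name, retained, excluded) partitions."""
    records = []
    for name, retained, excluded in stages:
        records.append(
            FunnelStage(
                name=name,
                n_in=len(retained) + len(excluded),
                n_excluded=len(excluded),
                n_out=len(retained),
                excluded_ids=tuple(excluded),
            )
        )
    return FunnelReport(records)


def run_screen(
    expr_a: ExpressionMatrix,
    target_tissue: str,
    annotation: set[str],
    omap: OrthologMap,
    expr_b: ExpressionMatrix,
    fold: float = 5.0,
    floor: float = 0.5,
) -> tuple[FunnelReport, dict[str, list[str]]]:
    """Run the full funnel and return (report, validated candidate->partners)."""
    calls = compute_specificity(expr_a, target_tissue, fold, floor)
    specific = [c.gene_id for c in calls if c.passes_fold]
    nonspecific = [c.gene_id for c in calls if not c.passes_fold]
    retained, excl_ann = filter_annotation(specific, annotation)
    mapped, excl_orth = map_orthologs(retained, omap)
    validated, rejected = cross_species_validate(
        mapped, expr_b, target_tissue, fold, floor
    )
    report = build_funnel_report(
        [
            ("specificity", specific, nonspecific),
            ("annotation", retained, excl_ann),
            ("ortholog", list(mapped), excl_orth),
            ("cross_species", list(validated), list(rejected)),
        ]
    )
    return report, validated
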