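"""Expression-compendium screen: QC, housekeeping normalisation, ranking.

A compendium of tab-delimited expression matrices (one gene per row, one
condition per column) is screened for datasets in which a query gene varies
most.  Datasets with too few genes, irregular expression (extreme
fold-change between conditions) or a missing query gene are rejected; for
the rest, the query's profile is normalised against the mean of a set of
housekeeping genes and datasets are ranked by the variance of that relative
profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "ScreenConfig",
    "RelativeProfile",
    "DatasetRanking",
    "ParseError",
    "read_expression_matrix",
    "write_expression_matrix",
    "qc_filter",
    "relative_profile",
    "variance_rank",
    "max_fold_change",
]


class ParseError(ValueError):
    """Malformed expression matrix file."""


@dataclass(frozen=True)
class ScreenConfig:
    """Screen parameters.

    Defaults mirror the screen as run for the BTN1 query: systematic name
    YJL059W, housekeeping genes ACT1 (YFL039C) and PDA1 (YER178W), datasets
    with fewer than 4000 genes or any between-condition linear fold change
    above 100 excluded, top 15 by variance kept.
    """

    query_gene: str = "YJL059W"
    housekeeping_genes: tuple[str, ...] = ("YFL039C", "YER178W")
    min_genes: int = 4000
    max_abs_fold: float = 100.0
    top_n: int = 15
    value_scale: str = "log2_ratio"  # or "linear_ratio"
    control_label: str | None = None

    def __post_init__(self) -> None:
        if self.min_genes <= 0:
            raise ValueError("min_genes must be positive")
        if self.max_abs_fold <= 1:
            raise ValueError("max_abs_fold must exceed 1")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.value_scale not in ("log2_ratio", "linear_ratio"):
            raise ValueError(f"unknown value_scale {self.value_scale!r}")


@dataclass
class ExpressionDataset:
    """Gene x condition expression matrix with a missing-value mask."""

    dataset_id: str
    gene_ids: list[str]
    condition_labels: list[str]
    control_index: int
    values: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.shape != (len(self.gene_ids), len(self.condition_labels)):
            raise ValueError("values shape inconsistent with gene/condition lists")
        if self.missing.shape != self.values.shape:
            raise ValueError("missing mask shape mismatch")
        if len(set(self.condition_labels)) != len(self.condition_labels):
            raise ValueError("condition labels must be unique")
        if not 0 <= self.control_index < len(self.condition_labels):
            raise ValueError("control_index out of range")
        if not np.isfinite(self.values[~self.missing]).all():
            raise ValueError("non-missing values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def row(self, gene: str) -> np.ndarray | None:
        """Values for one gene with missing entries as NaN, or None."""
        try:
            i = self.gene_ids.index(gene.upper())
        except ValueError:
            return None
        vals = self.values[i].copy()
        vals[self.missing[i]] = np.nan
        return vals


def _control_index(labels: list[str], config: ScreenConfig) -> int:
    targets = (
        [config.control_label.lower()] if config.control_label
        else ["control", "0 min"]
    )
    for i, lab in enumerate(labels):
        if lab.strip().lower() in targets:
            return i
    if config.control_label is not None:
        raise ParseError(f"control label {config.control_label!r} not found")
    return 0


def read_expression_matrix(
    path: str | Path, dataset_id: str, config: ScreenConfig
) -> ExpressionDataset:
    """Parse a tab-delimited matrix (first column GENE, empty cell = missing).

    Replicate columns sharing a label are averaged at load time; gene IDs
    are upper-cased for matching.
    """
    path = Path(path)
    try:
        lines = path.read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise ParseError(f"{path}: unreadable ({exc})") from exc
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: line 1: need a GENE column and >= 1 condition")
    raw_labels = [h.strip() for h in header[1:]]
    genes: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"{path}: line {lineno}: expected {len(header)} columns, "
                f"got {len(fields)}"
            )
        genes.append(fields[0].strip().upper())
        vals = []
        for j, cell in enumerate(fields[1:], start=2):
            cell = cell.strip()
            if cell == "":
                vals.append(np.nan)
            else:
                try:
                    vals.append(float(cell))
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {lineno}: bad value {cell!r}"
                    ) from exc
        rows.append(vals)
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ParseError(f"{path}: duplicate gene IDs: {dupes[:5]}")
    raw = np.array(rows, dtype=float) if rows else np.empty((0, len(raw_labels)))
    # average replicate columns sharing a label, ignoring missing replicates
    labels = list(dict.fromkeys(raw_labels))
    cols = []
    for lab in labels:
        idx = [j for j, l in enumerate(raw_labels) if l == lab]
        block = raw[:, idx]
        n_obs = (~np.isnan(block)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            col = np.nansum(block, axis=1) / np.where(n_obs > 0, n_obs, 1)
        cols.append(np.where(n_obs > 0, col, np.nan))
    values = np.column_stack(cols) if cols else raw
    missing = np.isnan(values)
    values = np.where(missing, 0.0, values)
    return ExpressionDataset(
        dataset_id=dataset_id,
        gene_ids=genes,
        condition_labels=labels,
        control_index=_control_index(labels, config),
        values=values,
        missing=missing,
    )


def write_expression_matrix(dataset: ExpressionDataset, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("GENE\t" + "\t".join(dataset.condition_labels) + "\n")
        for i, gene in enumerate(dataset.gene_ids):
            cells = [
                "" if dataset.missing[i, j] else _fmt(dataset.values[i, j])
                for j in range(len(dataset.condition_labels))
            ]
            fh.write(gene + "\t" + "\t".join(cells) + "\n")


def _fmt(x: float) -> str:
    return f"{x:g}"


@dataclass(frozen=True)
class RelativeProfile:
    """Per-condition query expression relative to the housekeeping mean."""

    dataset_id: str
    values: np.ndarray
    variance: float


@dataclass
class DatasetRanking:
    kept: list[tuple[str, float | None]] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)


def _to_log2(values: np.ndarray, scale: str) -> np.ndarray:
    if scale == "log2_ratio":
        return values
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(values)
    out[~np.isfinite(out)] = np.nan  # non-positive linear values -> missing
    return out


def qc_filter(
    datasets: list[ExpressionDataset], config: ScreenConfig
) -> DatasetRanking:
    """Reject datasets by gene count, irregular folds, or a missing query.

    The fold rule compares, per gene, its most extreme pair of conditions
    on the linear scale; any gene exceeding ``max_abs_fold`` rejects the
    dataset.  Kept datasets are returned unranked (variance None).
    """
    ranking = DatasetRanking()
    for ds in datasets:
        if ds.n_genes < config.min_genes:
            ranking.rejected.append((ds.dataset_id, "too_few_genes"))
            continue
        log2 = _to_log2(np.where(ds.missing, np.nan, ds.values),
                        config.value_scale)
        with np.errstate(invalid="ignore"):
            span = np.nanmax(log2, axis=1) - np.nanmin(log2, axis=1)
        if np.any(2.0 ** span[np.isfinite(span)] > config.max_abs_fold):
            ranking.rejected.append((ds.dataset_id, "fold_out_of_range"))
            continue
        q = ds.row(config.query_gene)
        if q is None or np.isnan(q).all():
            ranking.rejected.append((ds.dataset_id, "query_missing"))
            continue
        ranking.kept.append((ds.dataset_id, None))
    return ranking


def relative_profile(
    dataset: ExpressionDataset, config: ScreenConfig
) -> RelativeProfile:
    """Query profile minus the housekeeping-gene mean, on the log2 scale.

    Conditions where the query or every housekeeping gene is missing are
    dropped; the variance is the sample variance over retained conditions.
    """
    q = dataset.row(config.query_gene)
    if q is None:
        raise ValueError(
            f"{dataset.dataset_id}: query gene {config.query_gene} absent"
        )
    q = _to_log2(q, config.value_scale)
    hk_rows = [r for g in config.housekeeping_genes
               if (r := dataset.row(g)) is not None]
    if not hk_rows:
        raise ValueError(f"{dataset.dataset_id}: no housekeeping gene present")
    hk = _to_log2(np.vstack(hk_rows), config.value_scale)
    with np.errstate(invalid="ignore"):
        hk_mean = np.nanmean(hk, axis=0)
    rel = q - hk_mean
    rel = rel[np.isfinite(rel)]
    if rel.size < 2:
        raise ValueError(
            f"{dataset.dataset_id}: fewer than 2 conditions with usable "
            "query and housekeeping values"
        )
    return RelativeProfile(
        dataset_id=dataset.dataset_id,
        values=rel,
        variance=float(np.var(rel, ddof=1)),
    )


def variance_rank(
    profiles: list[RelativeProfile], config: ScreenConfig
) -> DatasetRanking:
    """Top ``top_n`` datasets by relative-profile variance, descending.

    Ties break lexicographically on dataset_id for deterministic output.
    """
    order = sorted(profiles, key=lambda p: (-p.variance, p.dataset_id))
    kept = [(p.dataset_id, p.variance) for p in order[: config.top_n]]
    return DatasetRanking(kept=kept, rejected=[])


def max_fold_change(
    dataset: ExpressionDataset, config: ScreenConfig
) -> tuple[str, float]:
    """Condition with the query's highest linear fold vs the control column."""
    q = dataset.row(config.query_gene)
    if q is None:
        raise ValueError(f"query gene {config.query_gene} absent")
    ctrl = q[dataset.control_index]
    if np.isnan(ctrl):
        raise ValueError("query value missing at the control condition")
    if config.value_scale == "log2_ratio":
        folds = 2.0 ** (q - ctrl)
    else:
        folds = q / ctrl
    folds = np.where(np.isnan(folds), -np.inf, folds)
    best = int(np.argmax(folds))
    return dataset.condition_labels[best], float(folds[best])


def write_ranking_tsv(
    ranking: DatasetRanking,
    datasets: dict[str, ExpressionDataset],
    path: str | Path,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("dataset_id\tn_genes\tvariance\tkept\treason\n")
        for ds_id, var in ranking.kept:
            n = datasets[ds_id].n_genes if ds_id in datasets else ""
            v = "" if var is None else f"{var:.6g}"
            fh.write(f"{ds_id}\t{n}\t{v}\ttrue\t\n")
        for ds_id, reason in ranking.rejected:
            n = datasets[ds_id].n_genes if ds_id in datasets else ""
            fh.write(f"{ds_id}\t{n}\t\tfalse\t{reason}\n")


def write_profile_tsv(profile: RelativeProfile, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("dataset_id\tcondition_index\trelative_log2\n")
        for i, v in enumerate(profile.values):
            fh.write(f"{profile.dataset_id}\t{i}\t{v:.6g}\n")
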