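"""Cell-to-cell and cell-to-bulk variant concordance analytics.

Implements the replicate-comparison statistics used to judge single-cell
mtDNA call sets: pairwise intersection/union counts under allele-frequency
and depth thresholds, bulk confirmation, positive predictive value (treating
variants shared by technical replicates as true positives), Pearson
correlation of allele frequencies at shared sites, threshold sweeps, and the
multi-cell variant-by-cell tabulation with its summary statistics
(homoplasmic = mean AF strictly above 0.95; "shared by the majority" =
detected in strictly more than half of the cells).

Percentages follow the conventions of the source tables: pairwise
percentages carry two decimals, table summaries are rounded to the nearest
integer (half away from zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .call import VariantCall

VariantKey = tuple[int, str, str]

HOM_AF = 0.95


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _round2(x: float) -> float:
    return round(x + 1e-12, 2)


# ---------------------------------------------------------------------------
# call sets
# ---------------------------------------------------------------------------

@dataclass
class CallSet:
    """Variant calls of one sample: (pos, ref, alt) -> (AF, total depth)."""

    cell_id: str
    assay: str = "WGS"  # WGS | WES | ATAC | BULK
    variants: dict[VariantKey, tuple[float, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)

    def keys(self) -> set[VariantKey]:
        return set(self.variants)

    def af(self, key: VariantKey) -> float:
        return self.variants[key][0]

    @classmethod
    def from_calls(
        cls, calls: list[VariantCall], cell_id: str, assay: str = "WGS"
    ) -> "CallSet":
        return cls(
            cell_id,
            assay,
            {c.key(): (c.af, c.total) for c in calls},
        )

    @classmethod
    def from_vcf(cls, path: str | Path, cell_id: str, assay: str = "WGS") -> "CallSet":
        from .call import read_vcf

        return cls.from_calls(read_vcf(path), cell_id, assay)


def filter_callset(cs: CallSet, af_min: float, depth_min: int) -> CallSet:
    """Keep variants with AF >= af_min and total depth >= depth_min."""
    if af_min < 0 or depth_min < 0:
        raise ValueError("thresholds must be non-negative")
    kept = {
        k: (af, dp)
        for k, (af, dp) in cs.variants.items()
        if af >= af_min and dp >= depth_min
    }
    return CallSet(cs.cell_id, cs.assay, kept)


# ---------------------------------------------------------------------------
# pairwise concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseConcordance:
    all_count: int
    common: int
    hom: int
    het: int
    pct_common: float
    unique: int
    confirmed: int
    pct_confirmed: float
    degenerate: bool = False  # no common variants: pct_confirmed reported as 0

    def as_row(self) -> dict:
        return {
            "All": self.all_count,
            "Common": self.common,
            "Hom": self.hom,
            "Het": self.het,
            "%Common": self.pct_common,
            "Unique": self.unique,
            "Confirmed": self.confirmed,
            "%Confirmed": self.pct_confirmed,
        }


def pairwise(
    cs_a: CallSet,
    cs_b: CallSet,
    bulk: CallSet | None,
    af_min: float,
    depth_min: int,
) -> PairwiseConcordance:
    """Replicate concordance at the given thresholds (bulk filtered alike)."""
    a = filter_callset(cs_a, af_min, depth_min)
    b = filter_callset(cs_b, af_min, depth_min)
    bulk_keys = (
        filter_callset(bulk, af_min, depth_min).keys() if bulk is not None else set()
    )
    ka, kb = a.keys(), b.keys()
    union = ka | kb
    inter = ka & kb
    hom = sum(1 for k in inter if a.af(k) > HOM_AF and b.af(k) > HOM_AF)
    confirmed = len(inter & bulk_keys)
    n_all, n_common = len(union), len(inter)
    return PairwiseConcordance(
        all_count=n_all,
        common=n_common,
        hom=hom,
        het=n_common - hom,
        pct_common=_round2(100.0 * n_common / n_all) if n_all else 0.0,
        unique=n_all - n_common,
        confirmed=confirmed,
        pct_confirmed=_round2(100.0 * confirmed / n_common) if n_common else 0.0,
        degenerate=n_common == 0,
    )


def concordance_from_counts(all_count: int, common: int, confirmed: int) -> dict:
    """Recompute the percentage columns from a table's integer counts."""
    return {
        "%Common": _round2(100.0 * common / all_count) if all_count else 0.0,
        "%Confirmed": _round2(100.0 * confirmed / common) if common else 0.0,
    }


def ppv(common: int, per_cell_totals: list[int]) -> dict:
    """Per-cell precision (% of a cell's calls shared with its replicate)."""
    if any(t < common for t in per_cell_totals):
        raise ValueError("per-cell totals must each be >= the common count")
    per_cell = [
        _round2(100.0 * common / t) if t else 0.0 for t in per_cell_totals
    ]
    return {
        "per_cell_ppv": per_cell,
        "mean_ppv": _round2(float(np.mean(per_cell))) if per_cell else 0.0,
    }


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdGrid:
    af_thresholds: tuple[float, ...] = tuple(round(0.01 * i, 2) for i in range(1, 11))
    depth_thresholds: tuple[int, ...] = (10, 30, 50, 100, 500, 1000)

    def __post_init__(self) -> None:
        for seq in (self.af_thresholds, self.depth_thresholds):
            if not seq or any(t <= 0 for t in seq) or list(seq) != sorted(seq):
                raise ValueError("thresholds must be positive and ascending")


def sweep(
    cs_a: CallSet, cs_b: CallSet, bulk: CallSet | None, grid: ThresholdGrid
) -> pd.DataFrame:
    """Pairwise concordance at every (af_min, depth_min) grid point."""
    rows = []
    for af_min in grid.af_thresholds:
        for depth_min in grid.depth_thresholds:
            pc = pairwise(cs_a, cs_b, bulk, af_min, depth_min)
            rows.append({"af_min": af_min, "depth_min": depth_min, **pc.as_row()})
    return pd.DataFrame(rows)


def af_correlation(cs_a: CallSet, cs_b: CallSet) -> tuple[float, float]:
    """Pearson r (and two-sided p) of AFs at variants shared by both sets."""
    shared = sorted(cs_a.keys() & cs_b.keys())
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared variants, have {len(shared)}")
    x = [cs_a.af(k) for k in shared]
    y = [cs_b.af(k) for k in shared]
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# multi-cell tabulation
# ---------------------------------------------------------------------------

def variant_label(key: VariantKey) -> str:
    pos, ref, alt = key
    return f"m.{pos}{ref}>{alt}"


def tabulate_multicell(
    callsets: list[CallSet],
    bulk: CallSet | None,
    af_min: float = 0.03,
    depth_min: int = 30,
    min_cells: int = 2,
) -> pd.DataFrame:
    """Variant-by-cell table across assays.

    A variant enters the table when, after thresholding, it is detected in at
    least ``min_cells`` cells of at least one assay. Columns per assay:
    ``in_<assay>`` (cell count) and ``maf_<assay>`` (mean AF over detecting
    cells). ``is_in_bulk`` applies the same thresholds to the bulk;
    ``bulk_af`` reports the raw bulk AF regardless of bulk depth.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two single-cell call sets")
    filtered = [filter_callset(cs, af_min, depth_min) for cs in callsets]
    assays = sorted({cs.assay for cs in filtered})
    det: dict[VariantKey, dict[str, list[float]]] = {}
    for cs in filtered:
        for k, (af, _dp) in cs.variants.items():
            det.setdefault(k, {a: [] for a in assays})[cs.assay].append(af)
    bulk_filtered_keys = (
        filter_callset(bulk, af_min, depth_min).keys() if bulk is not None else set()
    )
    rows = []
    for k in sorted(det):
        counts = {a: len(det[k][a]) for a in assays}
        if max(counts.values()) < min_cells:
            continue
        row: dict = {"variant": variant_label(k), "pos": k[0], "ref": k[1], "alt": k[2]}
        for a in assays:
            row[f"in_{a}"] = counts[a]
            row[f"maf_{a}"] = (
                round(float(np.mean(det[k][a])), 4) if counts[a] else np.nan
            )
        row["is_in_bulk"] = int(k in bulk_filtered_keys)
        row["bulk_af"] = (
            round(bulk.af(k), 4) if bulk is not None and k in bulk.variants else 0.0
        )
        rows.append(row)
    return pd.DataFrame(rows)


def assay_view(table: pd.DataFrame, n_cells_col: str, maf_col: str) -> pd.DataFrame:
    """Normalize one assay's columns to (n_cells, mean_af, is_in_bulk)."""
    view = table[[n_cells_col, maf_col, "is_in_bulk"]].copy()
    view.columns = ["n_cells", "mean_af", "is_in_bulk"]
    view = view.dropna(subset=["n_cells"])
    view = view[view["n_cells"] > 0]
    view["n_cells"] = view["n_cells"].astype(int)
    return view


def table_stats(view: pd.DataFrame, n_cells: int, hom_af: float = HOM_AF) -> dict:
    """Summary of a variant-by-cell table (one assay's view).

    Homoplasmic or quasi-homoplasmic rows have mean AF strictly above
    ``hom_af``; "shared by the majority" means detected in strictly more than
    half of the ``n_cells`` cells.
    """
    if view.empty:
        raise ValueError("empty multi-cell table")
    hom_mask = view["mean_af"] > hom_af
    het = view.loc[~hom_mask, "mean_af"]
    majority = view["n_cells"] > n_cells / 2
    return {
        "n_variants": int(len(view)),
        "n_hom": int(hom_mask.sum()),
        "n_het": int((~hom_mask).sum()),
        "het_af_min": float(het.min()) if len(het) else None,
        "het_af_max": float(het.max()) if len(het) else None,
        "pct_bulk_confirmed": _round_half_up(100.0 * view["is_in_bulk"].mean()),
        "n_shared_by_majority": int(majority.sum()),
        "pct_shared_by_majority": _round_half_up(100.0 * majority.mean()),
    }


# ---------------------------------------------------------------------------
# packaged table transcriptions
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("scmito").joinpath("data", name)


def load_table1() -> pd.DataFrame:
    """Pairwise HT-29 concordance counts by amplification protocol."""
    with resources.as_file(_data_path("table1.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_table2() -> pd.DataFrame:
    """Variant-by-cell table, nine HT-29 cells (WGS + WES, eWGA protocol)."""
    with resources.as_file(_data_path("table2.tsv")) as p:
        return pd.read_csv(p, sep="\t", na_values=["-"])


def load_table3() -> pd.DataFrame:
    """Variant-by-cell table, 48 TF-1 cells (scATAC-seq)."""
    with resources.as_file(_data_path("table3.tsv")) as p:
        return pd.read_csv(p, sep="\t")
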