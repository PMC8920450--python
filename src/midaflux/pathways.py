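"""KEGG-pathway aggregation of protein synthesis rates.

Protein-level fractional synthesis rates are averaged within each pathway,
weighted by the number of peptide isotope measurements behind each protein
(pooled over the animals of a group), and pathways represented by fewer than
five measured proteins are dropped.  Treated/control and aged/young
fold-changes of the weighted means give the pathway-level flux signature;
the long-format table is the canonical output, with an optional heat-map
image as an untested convenience.

Aggregation works off a static accession -> pathway mapping table (TSV), so
the analysis path needs no KEGG REST access.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PathwayMap",
    "load_pathway_map",
    "pathway_aggregate",
    "pathway_fold_change",
    "age_contrast",
    "heatmap",
]

logger = logging.getLogger(__name__)

MIN_PROTEINS_DEFAULT = 5


@dataclass(frozen=True)
class PathwayMap:
    """Deduplicated many-to-many accession/pathway membership records."""

    records: pd.DataFrame  # columns: accession, pathway_id, pathway_name

    def __post_init__(self) -> None:
        req = {"accession", "pathway_id", "pathway_name"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"pathway map missing columns: {sorted(missing)}")
        dedup = self.records.drop_duplicates(["accession", "pathway_id"]).reset_index(drop=True)
        object.__setattr__(self, "records", dedup)

    def __len__(self) -> int:
        return len(self.records)


def load_pathway_map(source) -> PathwayMap:
    """Read an accession -> KEGG-pathway mapping (TSV or DataFrame).

    Malformed rows (wrong field count, empty accession) are skipped with a
    logged count; duplicate (accession, pathway) pairs collapse to one.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        rows, skipped = [], 0
        with open(source, "r", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) != len(header) or not parts[0].strip():
                    skipped += 1
                    continue
                rows.append(dict(zip(header, parts)))
        if skipped:
            logger.warning("skipped %d malformed rows in pathway map", skipped)
        df = pd.DataFrame(rows, columns=header)
    if df.empty:
        warnings.warn("pathway map is empty")
        df = pd.DataFrame(columns=["accession", "pathway_id", "pathway_name"])
    return PathwayMap(df)


def pathway_aggregate(
    proteins: pd.DataFrame,
    pathway_map: PathwayMap,
    *,
    min_proteins: int = MIN_PROTEINS_DEFAULT,
    value_col: str = "f",
    group_cols: tuple[str, ...] = ("age", "treatment"),
) -> pd.DataFrame:
    """Peptide-count-weighted pathway means of protein synthesis fractions.

    ``proteins`` is the per-animal protein FSR table and must carry
    ``n_peptides`` (the weights are mandatory).  Per protein and group the
    value is the mean over animals and the weight the pooled peptide count;
    per pathway the weighted mean is Sum(w_i * f_i) / Sum(w_i).  Pathways
    with fewer than ``min_proteins`` measured proteins are dropped.
    """
    if "n_peptides" not in proteins.columns:
        raise ValueError("protein table must carry peptide counts (column 'n_peptides')")
    gcols = [c for c in group_cols if c in proteins.columns]
    per_protein = (
        proteins.groupby(["accession", *gcols])
        .agg(value=(value_col, "mean"), weight=("n_peptides", "sum"))
        .reset_index()
    )
    joined = per_protein.merge(pathway_map.records, on="accession", how="inner")
    if joined.empty:
        return pd.DataFrame(
            columns=["pathway_id", "pathway_name", *gcols,
                     f"weighted_mean_{value_col}", "n_proteins", "n_peptides"]
        )
    out_rows = []
    for keys, sub in joined.groupby(["pathway_id", "pathway_name", *gcols], sort=True):
        w = sub["weight"].to_numpy(dtype=float)
        if (w <= 0).any():
            raise ValueError("pathway weights must be strictly positive")
        v = sub["value"].to_numpy(dtype=float)
        rec = dict(zip(["pathway_id", "pathway_name", *gcols], keys))
        rec[f"weighted_mean_{value_col}"] = float((w * v).sum() / w.sum())
        rec["n_proteins"] = int(sub["accession"].nunique())
        rec["n_peptides"] = int(w.sum())
        out_rows.append(rec)
    out = pd.DataFrame(out_rows)
    out = out[out["n_proteins"] >= min_proteins].reset_index(drop=True)
    return out


def pathway_fold_change(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    *,
    value_col: str = "weighted_mean_f",
) -> pd.DataFrame:
    """Per-pathway treated/control fold of the weighted means (inner join)."""
    keys = ["pathway_id", "pathway_name"]
    merged = treated[keys + [value_col, "n_proteins", "n_peptides"]].merge(
        control[keys + [value_col]],
        on=keys,
        how="inner",
        suffixes=("_treated", "_control"),
    )
    vt, vc = f"{value_col}_treated", f"{value_col}_control"
    folds, log2s, flags = [], [], []
    for _, row in merged.iterrows():
        if row[vc] <= 0:
            folds.append(float("nan"))
            log2s.append(float("nan"))
            flags.append("zero_control")
        else:
            fold = row[vt] / row[vc]
            folds.append(fold)
            log2s.append(math.log2(fold))
            flags.append("")
    merged["fold"] = folds
    merged["log2_fold"] = log2s
    merged["flag"] = flags
    return merged.sort_values("pathway_id").reset_index(drop=True)


def age_contrast(
    aged: pd.DataFrame,
    young: pd.DataFrame,
    *,
    value_col: str = "weighted_mean_f",
) -> pd.DataFrame:
    """Per-pathway aged/young ratio of weighted means under matched treatment.

    Both inputs must come from the same treatment condition; pathways present
    on only one side are excluded by the inner join.  A ratio of 1 maps to 0
    on the log2 scale (no change).
    """
    out = pathway_fold_change(aged, young, value_col=value_col)
    return out.rename(
        columns={
            f"{value_col}_treated": f"{value_col}_aged",
            f"{value_col}_control": f"{value_col}_young",
        }
    )


def heatmap(fold_table: pd.DataFrame, path, *, value_col: str = "log2_fold") -> None:
    """Render a one-column pathway heat map (convenience; the table is canonical)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = fold_table.sort_values(value_col, ascending=False)
    fig, ax = plt.subplots(figsize=(4, 0.4 * len(data) + 1.5))
    values = data[value_col].to_numpy(dtype=float)[:, None]
    vmax = np.nanmax(np.abs(values)) or 1.0
    im = ax.imshow(values, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_yticks(range(len(data)), data["pathway_name"])
    ax.set_xticks([])
    fig.colorbar(im, ax=ax, label=value_col)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
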