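"""ChIP-seq preprocessing: from per-TF binding-site coordinates to sample paths.

The pipeline mirrors a promoter-centric co-localization analysis:

1. For every gene, take the strand-oriented window from 8 kb upstream to
   2 kb downstream of the TSS and express each TF's site positions as
   offsets in [-8000, 2000] (negative = upstream).
2. Keep "informative" genes on which at least ``min_tfs`` distinct TFs have
   a site (default 8 of 14).
3. Build one analysis region per TF by either *pooling* — overlaying every
   gene's window onto a common interval, which assumes the TF's binding
   intensity is identical across genes — or *concatenating* — laying the
   gene windows end to end, which drops that assumption.  Either way the
   region is affinely mapped to [0, 10] for clustering.

Coordinate conventions: site intervals are BED-style 0-based half-open and
are reduced to their midpoint; the TSS table is 1-based and is converted to
the same 0-based axis internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nhpp import SamplePath

UPSTREAM = -8000.0
DOWNSTREAM = 2000.0
_WINDOW = DOWNSTREAM - UPSTREAM


@dataclass(frozen=True)
class TssRecord:
    gene_id: str
    chrom: str
    tss: int  # 1-based
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 1:
            raise ValueError(f"gene {self.gene_id}: TSS coordinate must be >= 1")


def read_tss_table(path) -> list:
    """Tab-separated TSS annotation: gene_id, chrom, tss (1-based), strand."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["gene_id", "chrom", "tss", "strand"], dtype={"chrom": str},
    )
    return [
        TssRecord(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]


def read_bed_sites(path, tf_name: str) -> pd.DataFrame:
    """BED site intervals (chrom, start, end[, name]) for one TF."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    df["chrom"] = df["chrom"].astype(str)
    df["tf"] = tf_name
    return df


def extract_upstream(tf_sites: pd.DataFrame, tss_records) -> pd.DataFrame:
    """Per-TF, per-gene site offsets within the oriented [-8000, 2000] window.

    ``tf_sites`` needs columns (tf, chrom, start, end); the site coordinate
    is the interval midpoint.  On the + strand the offset is site - TSS, on
    the - strand TSS - site, so the window always reads 5' to 3'.  Sites on
    chromosomes absent from the annotation are skipped (counted, not fatal).
    """
    sites = tf_sites.copy()
    sites["pos"] = (sites["start"] + sites["end"]) / 2.0
    rows = []
    for rec in tss_records:
        tss0 = rec.tss - 1  # to the 0-based axis of BED midpoints
        on_chrom = sites[sites["chrom"] == rec.chrom]
        if on_chrom.empty:
            continue
        offsets = on_chrom["pos"].to_numpy() - tss0
        if rec.strand == "-":
            offsets = -offsets
        keep = (offsets >= UPSTREAM) & (offsets <= DOWNSTREAM)
        for tf, off in zip(on_chrom["tf"].to_numpy()[keep], offsets[keep]):
            rows.append((tf, rec.gene_id, float(off)))
    out = pd.DataFrame(rows, columns=["tf", "gene", "offset"])
    return out.sort_values(["tf", "gene", "offset"], kind="stable").reset_index(drop=True)


def filter_genes(regionized: pd.DataFrame, min_tfs: int = 8) -> list:
    """Genes whose window holds sites of at least ``min_tfs`` distinct TFs."""
    if regionized.empty:
        return []
    counts = regionized.groupby("gene")["tf"].nunique()
    return sorted(counts.index[counts >= min_tfs])


def build_paths(
    regionized: pd.DataFrame,
    genes,
    strategy: str = "pooling",
    target_region=(0.0, 10.0),
) -> list:
    """Assemble one sample path per TF with the pooling or concatenating strategy.

    Pooling maps every gene window onto the full target interval and
    overlays the offsets; concatenating gives gene g (in lexicographic gene
    order) the sub-interval [L(g-1)/G, Lg/G] of the target.  Total site
    counts per TF are identical under both strategies.
    """
    if strategy not in ("pooling", "concatenating"):
        raise ValueError(f"unknown strategy {strategy!r}")
    lo, hi = float(target_region[0]), float(target_region[1])
    length = hi - lo
    genes = sorted(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    G = len(genes)
    data = regionized[regionized["gene"].isin(gene_index)]
    paths = []
    for tf in sorted(data["tf"].unique()):
        sub = data[data["tf"] == tf]
        frac = (sub["offset"].to_numpy() - UPSTREAM) / _WINDOW
        if strategy == "pooling":
            coords = lo + frac * length
        else:
            gidx = np.array([gene_index[g] for g in sub["gene"]])
            coords = lo + (gidx + frac) * length / G
        paths.append(SamplePath(np.clip(coords, lo, hi), label=tf))
    return paths


def summarize_paths(paths) -> pd.DataFrame:
    """Per-TF site count plus the six-number summary of site locations
    (min, Q1, median, mean, Q3, max; quartiles by linear interpolation)."""
    rows = []
    for p in paths:
        if p.n == 0:
            rows.append([p.label, 0] + [np.nan] * 6)
            continue
        q1, med, q3 = np.quantile(p.sites, [0.25, 0.5, 0.75])
        rows.append(
            [p.label, p.n, p.sites.min(), q1, med, p.sites.mean(), q3, p.sites.max()]
        )
    return pd.DataFrame(
        rows, columns=["tf", "n_sites", "min", "q1", "median", "mean", "q3", "max"]
    )


def write_regionized(regionized: pd.DataFrame, path) -> None:
    regionized.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_regionized(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"tf": str, "gene": str}, float_precision="round_trip"
    )
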