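"""Plain-text readers and writers for sample paths and result tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .nhpp import SamplePath


def write_sample_paths(paths, path) -> None:
    """Tab-separated site list, one row per site: tf_name, coordinate.

    Coordinates are written with full precision so a read/write cycle
    round-trips exactly.
    """
    with open(path, "w") as fh:
        fh.write("tf\tcoordinate\n")
        for p in paths:
            for s in p.sites:
                fh.write(f"{p.label}\t{float(s)!r}\n")


def read_sample_paths(path) -> list:
    """Inverse of `write_sample_paths`; TF order follows first appearance.

    A TF appearing in the header-only file (no rows) yields no path: empty
    paths cannot be represented in a site list and must be tracked upstream.
    """
    df = pd.read_csv(path, sep="\t", dtype={"tf": str}, float_precision="round_trip")
    paths = []
    for tf in dict.fromkeys(df["tf"]):
        sites = df.loc[df["tf"] == tf, "coordinate"].to_numpy(dtype=float)
        paths.append(SamplePath(sites, label=tf))
    return paths


def write_assignments(labels, names, path) -> None:
    """Per-TF cluster index table."""
    with open(path, "w") as fh:
        fh.write("tf\tcluster\n")
        for name, lab in zip(names, labels):
            fh.write(f"{name}\t{int(lab)}\n")


def write_eval_summary(rows, path) -> None:
    """Tab-separated evaluation summary: method, scenario, T, AMCR, PPC."""
    with open(path, "w") as fh:
        fh.write("method\tscenario\tT\tamcr\tppc\n")
        for method, scenario, T, amcr, ppc in rows:
            fh.write(f"{method}\t{scenario}\t{T}\t{amcr:.6f}\t{ppc:.6f}\n")
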