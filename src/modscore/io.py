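"""Plain-text I/O for every stage: count tables, MTX matrices, TIFF fields.

Bulk counts travel as a genes x samples CSV plus samples.tsv / lengths.tsv
sidecars; single-cell matrices as MatrixMarket (cells x genes) with
barcodes.tsv and features.tsv sidecars (mitochondrial genes recognized by the
"MT-" prefix); images as one 16-bit grayscale TIFF per channel.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

from .bulk import CountMatrix
from .imaging import ChannelField
from .sc import CellMatrix

MITO_PREFIX = "MT-"


def write_bulk(m: CountMatrix, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m.counts.to_csv(outdir / "counts.csv", index_label="gene")
    m.condition.rename("condition").to_csv(
        outdir / "samples.tsv", sep="\t", index_label="sample_id"
    )
    m.gene_lengths.rename("length").to_csv(
        outdir / "lengths.tsv", sep="\t", index_label="gene"
    )


def read_bulk(indir: str | Path) -> CountMatrix:
    indir = Path(indir)
    counts = pd.read_csv(indir / "counts.csv", index_col="gene")
    samples = pd.read_csv(indir / "samples.tsv", sep="\t", index_col="sample_id")
    lengths = pd.read_csv(indir / "lengths.tsv", sep="\t", index_col="gene")
    return CountMatrix(
        counts=counts,
        gene_lengths=lengths["length"],
        condition=samples["condition"],
    )


def write_sc(m: CellMatrix, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(m.counts))
    pd.Series(m.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.Series(m.gene_symbols).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    if m.labels is not None:
        m.labels.rename("label").to_csv(outdir / "labels.tsv", sep="\t", index_label="cell_id")


def read_sc(indir: str | Path) -> CellMatrix:
    indir = Path(indir)
    counts = sparse.csr_matrix(spio.mmread(str(indir / "matrix.mtx")))
    cell_ids = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    symbols = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].tolist()
    mito_mask = np.array([s.startswith(MITO_PREFIX) for s in symbols])
    labels = None
    labels_path = indir / "labels.tsv"
    if labels_path.exists():
        labels = pd.read_csv(labels_path, sep="\t", index_col="cell_id")["label"]
    return CellMatrix(
        counts=counts,
        cell_ids=cell_ids,
        gene_symbols=symbols,
        mito_mask=mito_mask,
        labels=labels,
    )


def write_field(field: ChannelField, outdir: str | Path, name: str = "field", t: int = 0) -> None:
    """One 16-bit grayscale TIFF per channel: ``{name}_{channel}_{t}.tif``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for channel, img in field.channels.items():
        tifffile.imwrite(
            outdir / f"{name}_{channel}_{t}.tif", np.asarray(img, dtype=np.uint16)
        )


def read_field(indir: str | Path, name: str = "field", t: int = 0) -> ChannelField:
    indir = Path(indir)
    channels: Dict[str, np.ndarray] = {}
    for path in sorted(indir.glob(f"{name}_*_{t}.tif")):
        channel = path.stem[len(name) + 1 : -(len(str(t)) + 1)]
        channels[channel] = tifffile.imread(path)
    if not channels:
        raise FileNotFoundError(f"no TIFF channels for field {name!r} t={t} in {indir}")
    return ChannelField(channels=channels, timepoint=float(t))


def read_signature(path: str | Path) -> list[str]:
    """Gene list, one symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
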