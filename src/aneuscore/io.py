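"""Readers and writers for the on-disk formats used between pipeline stages.

Count matrices travel as a 10x-style Matrix Market triplet (matrix.mtx with
genes as rows, features.tsv, barcodes.tsv) plus a two-column cell-label TSV;
gene positions, karyotype truth, copy-number profiles, deviation tables and
calls are plain TSV; growth input is CSV with either caliper axes or areas.
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .cnv import CopyNumberProfile
from .growth import GrowthSeries, projected_area
from .preprocess import _dense
from .scoring import AneuploidyCall, DeviationTable

FLOAT_FMT = "%.10g"


def write_triplet(adata: ad.AnnData, outdir: str) -> None:
    """Write matrix.mtx (genes x cells), features.tsv, barcodes.tsv, labels.tsv."""
    os.makedirs(outdir, exist_ok=True)
    X = sparse.csr_matrix(_dense(adata.X).T.astype(np.int64))
    spio.mmwrite(os.path.join(outdir, "matrix.mtx"), X)
    mito = adata.var["mito"].astype(int) if "mito" in adata.var else 0
    feats = pd.DataFrame({
        "gene_id": adata.var_names,
        "gene_name": adata.var_names,
        "mito": mito if np.ndim(mito) else np.zeros(adata.n_vars, int),
    })
    feats.to_csv(os.path.join(outdir, "features.tsv"), sep="\t",
                 header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), header=False, index=False)
    pd.DataFrame({"barcode": adata.obs_names,
                  "group": adata.obs["group"].to_numpy()}).to_csv(
        os.path.join(outdir, "labels.tsv"), sep="\t", index=False)


def read_triplet(indir: str) -> ad.AnnData:
    """Read the triplet written by :func:`write_triplet` into an AnnData."""
    X = spio.mmread(os.path.join(indir, "matrix.mtx")).T.tocsr()
    feats = pd.read_csv(os.path.join(indir, "features.tsv"), sep="\t",
                        header=None, names=["gene_id", "gene_name", "mito"])
    barcodes = pd.read_csv(os.path.join(indir, "barcodes.tsv"),
                           header=None)[0].astype(str)
    var = pd.DataFrame(index=pd.Index(feats["gene_id"].astype(str),
                                      name="gene_id"))
    var["mito"] = feats["mito"].astype(bool).to_numpy()
    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    labels_path = os.path.join(indir, "labels.tsv")
    if os.path.exists(labels_path):
        labels = pd.read_csv(labels_path, sep="\t").set_index("barcode")
        obs["group"] = labels.loc[barcodes, "group"].to_numpy()
    return ad.AnnData(X=np.asarray(X.todense(), dtype=np.int64),
                      obs=obs, var=var)


def write_positions(positions: pd.DataFrame, path: str) -> None:
    positions.to_csv(path, sep="\t", index=False)


def read_positions(path: str) -> pd.DataFrame:
    pos = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"gene_id", "chromosome", "start", "end"}
    missing = required - set(pos.columns)
    if missing:
        raise ValueError(f"position table missing columns: {sorted(missing)}")
    return pos


def write_truth(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index_label="cell_id", float_format=FLOAT_FMT)


def write_profile(profile: CopyNumberProfile, outdir: str) -> None:
    """Dense cells x segments TSV plus a segment -> chromosome map."""
    os.makedirs(outdir, exist_ok=True)
    pd.DataFrame(profile.values, index=profile.cell_ids,
                 columns=profile.segment_ids).to_csv(
        os.path.join(outdir, "profile.tsv"), sep="\t",
        index_label="cell_id", float_format=FLOAT_FMT)
    pd.DataFrame({
        "segment": profile.segment_ids,
        "chromosome": profile.segment_chromosome,
        "start": profile.segment_start,
    }).to_csv(os.path.join(outdir, "segments.tsv"), sep="\t", index=False)
    pd.DataFrame({"barcode": profile.cell_ids,
                  "group": profile.cell_group}).to_csv(
        os.path.join(outdir, "labels.tsv"), sep="\t", index=False)


def read_profile(indir: str) -> CopyNumberProfile:
    values = pd.read_csv(os.path.join(indir, "profile.tsv"), sep="\t",
                         index_col="cell_id")
    segments = pd.read_csv(os.path.join(indir, "segments.tsv"), sep="\t",
                           dtype={"chromosome": str})
    labels = pd.read_csv(os.path.join(indir, "labels.tsv"), sep="\t")
    return CopyNumberProfile(
        values=values.to_numpy(dtype=float),
        cell_ids=values.index.astype(str),
        cell_group=labels["group"].to_numpy().astype(str),
        segment_ids=pd.Index(segments["segment"].astype(str)),
        segment_chromosome=segments["chromosome"].to_numpy(),
        segment_start=segments["start"].to_numpy(dtype=int),
    )


def write_scores(table: DeviationTable, call: AneuploidyCall,
                 outdir: str) -> None:
    """calls.tsv, deviations.tsv, and a per-group / per-chromosome summary."""
    os.makedirs(outdir, exist_ok=True)
    pd.DataFrame({
        "cell": table.D.index,
        "group": table.cell_group.to_numpy(),
        "aneuploid": call.aneuploid.to_numpy(),
        "flagged_chromosomes": [",".join(f) for f in call.flagged_chromosomes],
    }).to_csv(os.path.join(outdir, "calls.tsv"), sep="\t", index=False)
    table.D.to_csv(os.path.join(outdir, "deviations.tsv"), sep="\t",
                   index_label="cell", float_format=FLOAT_FMT)
    rows = []
    for g in pd.unique(table.cell_group):
        mask = (table.cell_group == g).to_numpy()
        row = {"group": g, "n_cells": int(mask.sum()),
               "aneuploid_fraction": float(call.aneuploid[mask].mean())}
        for c in table.outlier.columns:
            row[f"flag_rate_chr{c}"] = float(table.outlier.loc[mask, c].mean())
        rows.append(row)
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "summary.tsv"), sep="\t",
                              index=False, float_format=FLOAT_FMT)


def read_growth_csv(path: str) -> list[GrowthSeries]:
    """Load per-subject growth series from CSV.

    Columns: subject_id, day, and either area_mm2 or length_mm + width_mm
    (converted via the elliptical projected-area formula).
    """
    df = pd.read_csv(path)
    if "area_mm2" not in df.columns:
        if not {"length_mm", "width_mm"} <= set(df.columns):
            raise ValueError(
                "growth CSV needs area_mm2 or length_mm + width_mm columns")
        df["area_mm2"] = [
            projected_area(l, w) if l > 0 and w > 0 else 0.0
            for l, w in zip(df["length_mm"], df["width_mm"])]
    series = []
    for sid, sub in df.groupby("subject_id", sort=True):
        sub = sub.sort_values("day")
        series.append(GrowthSeries(subject_id=str(sid),
                                   time=sub["day"].to_numpy(dtype=float),
                                   area=sub["area_mm2"].to_numpy(dtype=float)))
    return series
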