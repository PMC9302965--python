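"""Readers/writers for the plain-text formats the pipeline consumes.

Supported inputs: ENCODE narrowPeak (10 columns), BED3 fragment files,
BED blacklists, and headered TSV tables (TSS, genomic features, peak/gene
count matrices, motif enrichment results, expression counts).  Files may be
plain or gzip-compressed (detected by ``.gz`` suffix).

Chromosome Y records are dropped at parse time by default, mirroring
analyses restricted to the whole genome excluding chrY.
"""

from __future__ import annotations

import gzip
import io
import logging
from pathlib import Path
from typing import Iterator

import pandas as pd

from .intervals import (
    FeatureInterval,
    FormatError,
    Fragment,
    GenomicInterval,
    Peak,
    PeakSet,
    TssRecord,
    ValidationError,
)

log = logging.getLogger(__name__)

_CHRY = {"chrY", "Y", "chry"}

TABLE_KINDS = ("tss", "features", "blacklist", "counts", "motifs", "expression")


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _fmt_float(x: float) -> str:
    """Format a float the way narrowPeak writers conventionally do."""
    return f"{x:g}"


def read_narrowpeak(path, drop_chry: bool = True, sample_id: str | None = None) -> PeakSet:
    """Parse an ENCODE narrowPeak file into a :class:`PeakSet`.

    The peak score used downstream is column 8 (-log10 p-value).  The summit
    is ``start + column 10``; a summit offset of -1 is rejected because the
    fixed-width stage requires a summit.
    """
    sample = sample_id if sample_id is not None else Path(path).name.split(".")[0]
    peaks: list[Peak] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 10:
                raise FormatError(
                    f"{path}:{lineno}: narrowPeak requires >=10 columns, got {len(cols)}"
                )
            chrom = cols[0]
            if drop_chry and chrom in _CHRY:
                continue
            try:
                start, end = int(cols[1]), int(cols[2])
                col5 = float(cols[4])
                signal = float(cols[6])
                pval = float(cols[7])
                qval = float(cols[8])
                offset = int(cols[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if offset == -1:
                raise ValidationError(
                    f"{path}:{lineno}: summit offset -1; a summit is required"
                )
            try:
                peaks.append(
                    Peak(
                        interval=GenomicInterval(chrom, start, end),
                        summit=start + offset,
                        score=pval,
                        sample_id=sample,
                        name=cols[3],
                        strand=cols[5],
                        signal=signal,
                        qvalue=qval,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            # column 5 is carried only for round-tripping
            peaks[-1] = _attach_col5(peaks[-1], col5)
    return PeakSet(sample_id=sample, peaks=peaks)


def _attach_col5(peak: Peak, col5: float) -> Peak:
    object.__setattr__(peak, "_col5", col5)
    return peak


def _get_col5(peak: Peak) -> float:
    return getattr(peak, "_col5", min(1000.0, peak.score * 10))


def write_narrowpeak(peakset: PeakSet, path, score_field: str = "score") -> None:
    """Write a :class:`PeakSet` as 10-column narrowPeak.

    ``score_field='spm'`` puts the SPM value in the p-value slot (column 8),
    which is where this pipeline keeps the score it ranks by.
    """
    with open(path, "wt") as fh:
        for p in peakset:
            pval = p.spm if (score_field == "spm" and p.spm is not None) else p.score
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        _fmt_float(_get_col5(p)),
                        p.strand,
                        _fmt_float(p.signal),
                        _fmt_float(pval),
                        _fmt_float(p.qvalue),
                        str(p.summit - p.start),
                    ]
                )
                + "\n"
            )


def read_fragments(path, drop_chry: bool = True) -> list[Fragment]:
    """Parse a BED3(+) fragment file; fragment length = end - start."""
    fragments: list[Fragment] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(
                    f"{path}:{lineno}: BED3 requires >=3 columns, got {len(cols)}"
                )
            chrom = cols[0]
            if drop_chry and chrom in _CHRY:
                continue
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            try:
                fragments.append(Fragment(GenomicInterval(chrom, start, end)))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return fragments


def write_fragments(fragments, path) -> None:
    with open(path, "wt") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")


def read_tables(path, kind: str, drop_chry: bool = True):
    """Read one of the typed TSV/BED tables.

    kind:
      - ``tss``        -> list[TssRecord]          (gene_id, chrom, pos, strand)
      - ``features``   -> list[FeatureInterval]    (chrom, start, end, label)
      - ``blacklist``  -> list[GenomicInterval]    (BED3+, no header)
      - ``counts``     -> DataFrame indexed by id  (id, <sample>...)
      - ``motifs``     -> DataFrame                (motif_id, tf_gene, p_value, fdr)
      - ``expression`` -> DataFrame indexed by gene_id
    """
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {TABLE_KINDS}")

    if kind == "blacklist":
        out = []
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                cols = line.split("\t")
                if len(cols) < 3:
                    raise FormatError(f"{path}:{lineno}: blacklist BED needs >=3 columns")
                if drop_chry and cols[0] in _CHRY:
                    continue
                out.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2])))
        return out

    df = pd.read_csv(path, sep="\t", dtype={0: str})

    if kind == "tss":
        _require_columns(df, ("gene_id", "chrom", "pos", "strand"), path)
        recs = [
            TssRecord(str(r.gene_id), str(r.chrom), int(r.pos), str(r.strand))
            for r in df.itertuples()
        ]
        if drop_chry:
            recs = [r for r in recs if r.chrom not in _CHRY]
        return recs

    if kind == "features":
        _require_columns(df, ("chrom", "start", "end", "label"), path)
        feats = []
        for r in df.itertuples():
            if drop_chry and str(r.chrom) in _CHRY:
                continue
            feats.append(
                FeatureInterval(
                    GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
                    str(r.label),
                )
            )
        return feats

    if kind == "motifs":
        _require_columns(df, ("motif_id", "tf_gene", "p_value", "fdr"), path)
        return df

    # counts / expression: first column is the row id
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dups = df.loc[df[id_col].duplicated(), id_col].iloc[0]
        raise ValidationError(f"{path}: duplicate row id {dups!r} in {kind} table")
    return df.set_index(id_col)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def iter_bed_lines(path) -> Iterator[str]:
    with _open_text(path) as fh:
        yield from fh
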