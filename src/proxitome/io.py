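"""Readers and writers for every tabular and genomic format the pipeline uses.

Formats owned here: TSV/CSV abundance matrices as exported by search-engine
software (blank, "NA", "NaN" and 0 all mean missing), sample-metadata TSV,
plain-text gene lists (optionally scored), ortholog-mapping TSV, BED3,
bedGraph and chrom.sizes. All readers validate and raise
:class:`~proxitome.errors.ValidationError` naming the offending entity;
nothing is silently coerced. Write -> read round trips are identity.

The TSV dialect throughout is tab-separated UTF-8 with ``#``-prefixed
comment lines ignored; ``.csv`` paths switch the delimiter to a comma.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .containers import AbundanceMatrix, GeneList, OrthologMap
from .errors import ValidationError
from .genome import ChromSizes, PeakSet, SignalTrack

MISSING_TOKENS = ["", "NA", "NaN", "nan", "na"]


def _sep_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _read_table(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise ValidationError(f"file not found: {path}")
    return pd.read_csv(
        path, sep=_sep_for(path), comment="#", dtype=str,
        keep_default_na=False, na_values=[], encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# abundance matrix + metadata


def read_sample_metadata(path: str) -> pd.DataFrame:
    meta = _read_table(path)
    required = ("sample_id", "condition", "experiment", "replicate")
    for col in required:
        if col not in meta.columns:
            raise ValidationError(f"metadata {path}: missing column {col!r}")
    if meta["sample_id"].duplicated().any():
        dupes = sorted(set(meta.loc[meta["sample_id"].duplicated(), "sample_id"]))
        raise ValidationError(f"metadata {path}: duplicate sample ids {dupes}")
    meta = meta.set_index("sample_id")
    meta["replicate"] = meta["replicate"].astype(int)
    return meta


def read_abundance_table(path: str, metadata_path: str,
                         protein_col: str | None = None) -> AbundanceMatrix:
    """Read a wide protein x sample intensity table plus its metadata.

    The first column (or ``protein_col``) holds protein accessions; every
    other column is a sample. Blank cells, "NA"/"NaN" and the value 0 are
    all treated as missing. Column layouts of search-engine exports vary,
    hence the configurable id column.
    """
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise ValidationError(f"{path}: need an id column plus >=1 sample column")
    id_col = protein_col if protein_col is not None else raw.columns[0]
    if id_col not in raw.columns:
        raise ValidationError(f"{path}: protein column {id_col!r} not found")
    ids = raw[id_col].astype(str)
    if ids.duplicated().any():
        dupes = sorted(set(ids[ids.duplicated()]))
        raise ValidationError(f"{path}: duplicated protein ids {dupes}")
    values = raw.drop(columns=[id_col])
    values.index = pd.Index(ids, name="protein_id")
    for tok in MISSING_TOKENS:
        values = values.replace(tok, np.nan)
    values = values.astype(float)
    values = values.mask(values == 0)  # 0 intensity means not detected
    neg = values < 0
    if neg.any().any():
        col = neg.any().idxmax() if False else neg.any()[neg.any()].index[0]
        row = neg[col][neg[col]].index[0]
        raise ValidationError(
            f"{path}: negative intensity for protein {row!r} in sample {col!r}"
        )
    metadata = read_sample_metadata(metadata_path)
    return AbundanceMatrix(values=values, metadata=metadata)


def write_abundance_table(matrix: AbundanceMatrix, path: str,
                          metadata_path: str) -> None:
    out = matrix.values.copy()
    out.insert(0, "protein_id", out.index)
    out.to_csv(path, sep=_sep_for(path), index=False, float_format="%.10g",
               na_rep="")
    meta = matrix.metadata.copy()
    meta.insert(0, "sample_id", meta.index)
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene lists and ortholog maps


def read_gene_list(path: str, name: str | None = None) -> GeneList:
    """Read a plain-text gene list: one id per line, or ``id<TAB>score``."""
    if not os.path.exists(path):
        raise ValidationError(f"file not found: {path}")
    members: list[str] = []
    scores: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            members.append(parts[0])
            if len(parts) > 1 and parts[1].strip():
                try:
                    scores[parts[0]] = float(parts[1])
                except ValueError as exc:
                    raise ValidationError(
                        f"{path}:{lineno}: unparseable score {parts[1]!r}"
                    ) from exc
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    return GeneList(name=name, members=tuple(members),
                    scores=scores or None)


def write_gene_list(genes: GeneList, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in genes.members:
            score = genes.score_of(m)
            if score is None:
                fh.write(f"{m}\n")
            else:
                fh.write(f"{m}\t{score:g}\n")


def read_ortholog_map(path: str) -> OrthologMap:
    df = _read_table(path)
    for col in ("source_id", "target_id", "score"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    df = df[["source_id", "target_id", "score"]].copy()
    df["score"] = df["score"].astype(int)
    return OrthologMap(records=df.reset_index(drop=True))


def write_ortholog_map(omap: OrthologMap, path: str) -> None:
    omap.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genomic formats


def read_chrom_sizes(path: str) -> ChromSizes:
    if not os.path.exists(path):
        raise ValidationError(f"file not found: {path}")
    sizes: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: expected 'chrom\\tlength'")
            chrom, length = parts[0], parts[1]
            if chrom in sizes:
                raise ValidationError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
            try:
                sizes[chrom] = int(length)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: unparseable length {length!r}"
                ) from exc
    return ChromSizes(sizes=sizes)


def write_chrom_sizes(sizes: ChromSizes, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(path: str, sizes: ChromSizes | None = None,
             label: str | None = None) -> PeakSet:
    """Read a BED3+ file into a PeakSet (0-based half-open intervals)."""
    if not os.path.exists(path):
        raise ValidationError(f"file not found: {path}")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if s < 0 or s >= e:
                raise ValidationError(
                    f"{path}:{lineno}: invalid interval {parts[0]}:{s}-{e}"
                )
            chroms.append(parts[0]); starts.append(s); ends.append(e)
    peaks = PeakSet(np.array(chroms, dtype=object),
                    np.array(starts, dtype=np.int64),
                    np.array(ends, dtype=np.int64),
                    label=label or os.path.splitext(os.path.basename(path))[0])
    if sizes is not None:
        peaks.validate_against(sizes)
    return peaks


def write_bed(peaks: PeakSet, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c, s, e in zip(peaks.chroms, peaks.starts, peaks.ends):
            fh.write(f"{c}\t{s}\t{e}\n")


def read_bedgraph(path: str, sizes: ChromSizes | None = None) -> SignalTrack:
    if not os.path.exists(path):
        raise ValidationError(f"file not found: {path}")
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ValidationError(f"{path}:{lineno}: fewer than 4 bedGraph fields")
            try:
                s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: unparseable fields") from exc
            if s < 0 or s >= e:
                raise ValidationError(f"{path}:{lineno}: invalid interval {s}-{e}")
            if sizes is not None:
                if parts[0] not in sizes:
                    raise ValidationError(
                        f"{path}:{lineno}: unknown chromosome {parts[0]!r}"
                    )
                if e > sizes[parts[0]]:
                    raise ValidationError(
                        f"{path}:{lineno}: interval beyond chromosome end"
                    )
            per_chrom.setdefault(parts[0], []).append((s, e, v))
    data = {}
    for chrom, rows in per_chrom.items():
        arr = np.array(rows, dtype=float)
        data[chrom] = (arr[:, 0].astype(np.int64),
                       arr[:, 1].astype(np.int64), arr[:, 2])
    return SignalTrack(data=data)


def write_bedgraph(track: SignalTrack, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, s, e, v in track.to_lines():
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# results tables


def write_results(table: pd.DataFrame, path: str,
                  provenance: dict | None = None,
                  index: bool = True, index_label: str = "protein_id") -> None:
    """Write a results TSV with a ``#``-prefixed provenance header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# proxitome {_pkg_version}\n")
        for key in sorted(provenance or {}):
            fh.write(f"# {key}={provenance[key]}\n")
        table.to_csv(fh, sep="\t", index=index,
                     index_label=index_label if index else None,
                     float_format="%.10g", na_rep="NA")


def read_results(path: str, index_col: str | None = "protein_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if index_col is not None and index_col in df.columns:
        df = df.set_index(index_col)
    return df
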