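"""Sequence and manifest input, feature-matrix and model serialization.

Reads are accepted in FASTA or FASTQ, plain or gzip-compressed; all reads
of one sample (possibly spread over several files, e.g. paired-end mates
or lane splits) are pooled into a single :class:`ReadSet`, since features
are computed per sample on the pooled reads.  No quality filtering or
trimming is applied — any pre-processing is the caller's responsibility.
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReadSet",
    "SampleManifest",
    "ManifestEntry",
    "read_sequences",
    "read_manifest",
    "write_feature_matrix",
    "read_feature_matrix",
    "save_model",
    "load_model",
]

GZIP_MAGIC = b"\x1f\x8b"


@dataclass
class ReadSet:
    """All reads of one sample, pooled and uppercased."""

    sample_id: str
    sequences: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    paths: tuple[str, ...]
    label: Optional[str] = None


@dataclass
class SampleManifest:
    """Ordered mapping sample_id -> file path(s) -> optional class label."""

    entries: list[ManifestEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def labels(self) -> list[Optional[str]]:
        return [e.label for e in self.entries]

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    def distinct_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            if e.label is not None:
                seen.setdefault(e.label, None)
        return list(seen)


def _open_text(path: str | Path) -> io.TextIOBase:
    """Open plain or gzip-compressed text, detected by magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def _detect_format(handle: io.TextIOBase, path: Path) -> str:
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    if first == "":
        raise ValueError(f"empty sequence file: {path}")
    raise ValueError(
        f"cannot auto-detect format of {path}: first character {first!r} "
        "is neither '>' (FASTA) nor '@' (FASTQ)"
    )


def read_sequences(
    paths: str | Path | Sequence[str | Path],
    fmt: str = "auto",
    sample_id: str = "",
) -> ReadSet:
    """Read one or more FASTA/FASTQ files into a pooled :class:`ReadSet`.

    Parameters
    ----------
    paths
        A single path or a sequence of paths; all records are pooled.
    fmt
        ``"auto"`` (detect per file from the first record character),
        ``"fasta"`` or ``"fastq"``.
    sample_id
        Identifier attached to the returned read set.

    Sequences are uppercased; FASTQ quality lines are discarded.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    sequences: list[str] = []
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"sequence file not found: {path}")
        handle = _open_text(path)
        try:
            this_fmt = fmt if fmt != "auto" else _detect_format(handle, path)
            n_before = len(sequences)
            records = SeqIO.parse(handle, this_fmt)
            idx = 0
            try:
                for idx, rec in enumerate(records, start=1):
                    seq = str(rec.seq).upper()
                    if not seq:
                        raise ValueError("empty sequence")
                    sequences.append(seq)
            except ValueError as exc:
                raise ValueError(
                    f"malformed {this_fmt} record ~#{idx + 1} in {path}: {exc}"
                ) from exc
            if len(sequences) == n_before:
                raise ValueError(f"no sequence records in {path}")
        finally:
            handle.close()
    return ReadSet(sample_id=sample_id, sequences=sequences)


def read_manifest(path: str | Path) -> SampleManifest:
    """Parse a tab-separated sample manifest.

    Columns: ``sample_id``, ``paths`` (comma-joined file paths) and an
    optional ``label``.  A header line is required.  Relative paths are
    resolved against the manifest's own directory.
    """
    path = Path(path)
    entries: list[ManifestEntry] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "sample_id":
            raise ValueError(
                f"manifest {path}: expected header 'sample_id<TAB>paths[<TAB>label]', "
                f"got {header!r}"
            )
        has_label = len(header) >= 3
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"manifest {path} line {lineno}: missing path column")
            sid = fields[0]
            if sid in seen:
                raise ValueError(f"manifest {path}: duplicate sample_id {sid!r}")
            seen.add(sid)
            rel_paths = tuple(p for p in fields[1].split(",") if p)
            if not rel_paths:
                raise ValueError(f"manifest {path} line {lineno}: empty path field")
            resolved = tuple(
                str(p) if Path(p).is_absolute() else str(path.parent / p)
                for p in rel_paths
            )
            label = fields[2] if has_label and len(fields) >= 3 and fields[2] else None
            entries.append(ManifestEntry(sample_id=sid, paths=resolved, label=label))
    manifest = SampleManifest(entries=entries)
    labels = manifest.distinct_labels()
    if len(labels) > 2:
        raise ValueError(
            f"manifest {path}: more than two label values {labels!r}; "
            "only binary classification is supported"
        )
    return manifest


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    """Write a manifest in the TSV dialect :func:`read_manifest` parses."""
    has_label = any(e.label is not None for e in manifest.entries)
    with open(path, "w") as fh:
        fh.write("sample_id\tpaths" + ("\tlabel" if has_label else "") + "\n")
        for e in manifest.entries:
            row = f"{e.sample_id}\t{','.join(e.paths)}"
            if has_label:
                row += f"\t{e.label if e.label is not None else ''}"
            fh.write(row + "\n")


# --- feature-matrix TSV -----------------------------------------------------


def write_feature_matrix(fm, path: str | Path) -> None:
    """Write a feature matrix as TSV: first column sample_id, then one
    column per canonical feature name; values at full float precision."""
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    df.insert(0, "sample_id", fm.sample_ids)
    if fm.labels is not None:
        df.insert(1, "label", fm.labels)
    # default float formatting is shortest-round-trip repr: exact recovery
    df.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: str | Path):
    """Read a feature matrix TSV written by :func:`write_feature_matrix`."""
    from .features import FeatureMatrix

    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip"
    )
    labels = None
    if "label" in df.columns:
        labels = df["label"].to_numpy(dtype=np.int64)
        df = df.drop(columns=["label"])
    sample_ids = df["sample_id"].tolist()
    df = df.drop(columns=["sample_id"])
    return FeatureMatrix(
        sample_ids=sample_ids,
        feature_names=list(df.columns),
        values=df.to_numpy(dtype=np.float64),
        labels=labels,
    )


# --- model container --------------------------------------------------------


def save_model(model_dict: dict, path: str | Path) -> None:
    """Serialize a trained classifier container to a self-describing JSON file.

    The container schema (see :func:`dectico.selection.train_final`) holds
    the oligonucleotide length ``k``, feature type, normalization tag,
    selected feature identifiers, and the SVM parameters and support data
    needed to reproduce predictions exactly.
    """
    class NumpyEncoder(json.JSONEncoder):
        def default(self, obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return super().default(obj)

    with open(path, "w") as fh:
        json.dump(model_dict, fh, cls=NumpyEncoder, indent=1)


def load_model(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
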