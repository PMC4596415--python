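"""Oligonucleotide features: k-mer counts, ICO vectors, composition vectors.

The intrinsic correlation of oligonucleotides (ICO) of a sample, for a
fixed oligonucleotide length ``k``, splits every k-mer into two
consecutive parts ``i`` (length ``m``) and ``j`` (length ``n = k - m``)
and records, for every split ``m = 1 .. k-1``:

* a junction-ratio block ``f_ij = p_ij / (p_i * p_j)`` over all
  ``4^k`` (i, j) pairs, where ``p_ij`` is the occurrence frequency of
  the k-mer ``i·j`` and ``p_i``, ``p_j`` are the occurrence frequencies
  of ``i`` and ``j`` counted with independent sliding windows at
  lengths ``m`` and ``n``; and
* an average-mutual-information block
  ``I(i) = sum_j p_{j|i} * log2(p_ij / (p_i * p_j))`` over the ``4^m``
  prefixes ``i``, with ``p_{j|i}`` the conditional frequency of suffix
  ``j`` given prefix ``i`` among k-mers starting with ``i``.

All blocks are concatenated in split order, giving a vector of length
``(k-1) * 4^k + sum_{m=1}^{k-1} 4^m``.  Counting pools all reads of a
sample (the sample is treated as one integrated sequence set), uses
overlapping windows with stride 1 that never span read boundaries, and
skips windows containing any non-A/C/G/T letter.

Zero conventions: if a junction count is zero its ``f_ij`` is 0 and its
``I(i)`` term is 0 (``0 * log 0 = 0``); if ``p_i`` or ``p_j`` is zero,
every ``f_ij`` and ``I(i)`` term involving it is 0.  An optional
pseudocount (added to every cell of every count table) is exposed for
sensitivity analysis and defaults to 0.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .seq_io import ReadSet, SampleManifest, read_sequences

__all__ = [
    "KmerCountTable",
    "IcoVector",
    "CompositionVector",
    "FeatureMatrix",
    "count_kmers",
    "composition_vector",
    "ico_vector",
    "ico_dimension",
    "ico_feature_names",
    "composition_feature_names",
    "minmax_normalize",
    "build_feature_matrix",
]

logger = logging.getLogger(__name__)

BASES = "ACGT"

# byte -> base code; -1 marks any letter outside A/C/G/T (N, IUPAC codes, ...)
_LUT = np.full(256, -1, dtype=np.int8)
for _idx, _b in enumerate(BASES):
    _LUT[ord(_b)] = _idx
    _LUT[ord(_b.lower())] = _idx


def _encode_reads(reads: ReadSet) -> np.ndarray:
    """Concatenate all reads into one int8 code array, separated by -1
    sentinels so that sliding windows never span read boundaries."""
    if not reads.sequences:
        return np.full(0, -1, dtype=np.int8)
    parts: list[np.ndarray] = []
    sep = np.full(1, -1, dtype=np.int8)
    for seq in reads.sequences:
        parts.append(_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)])
        parts.append(sep)
    return np.concatenate(parts[:-1])


def _count_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Count valid overlapping k-windows in a code array; returns a
    length-4^k int64 vector indexed by lexicographic k-mer rank."""
    counts = np.zeros(4 ** k, dtype=np.int64)
    if codes.size < k:
        return counts
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    if not valid.any():
        return counts
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    ranks = win[valid].astype(np.int64) @ powers
    np.add.at(counts, ranks, 1)
    return counts


@lru_cache(maxsize=None)
def _kmer_strings(k: int) -> tuple[str, ...]:
    return tuple("".join(p) for p in itertools.product(BASES, repeat=k))


@dataclass
class KmerCountTable:
    """Aggregated counts of all length-k windows over one sample's reads."""

    k: int
    counts: np.ndarray  # length 4^k, lexicographic A<C<G<T

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, kmer: str) -> int:
        rank = 0
        for ch in kmer:
            rank = rank * 4 + BASES.index(ch)
        return int(self.counts[rank])

    def to_dict(self) -> dict[str, int]:
        """Nonzero counts as a {kmer: count} mapping."""
        names = _kmer_strings(self.k)
        nz = np.nonzero(self.counts)[0]
        return {names[i]: int(self.counts[i]) for i in nz}


@dataclass
class CompositionVector:
    """Occurrence frequency of every length-k oligonucleotide."""

    k: int
    values: np.ndarray

    @property
    def names(self) -> list[str]:
        return composition_feature_names(self.k)


@dataclass
class IcoVector:
    """Concatenated f- and I-blocks over all (m, n) splits of a k-mer."""

    k: int
    values: np.ndarray

    @property
    def names(self) -> list[str]:
        return ico_feature_names(self.k)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FeatureMatrix:
    """Samples x named feature components, with optional {+1,-1} labels."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError(
                f"feature matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self.sample_ids),):
                raise ValueError("labels do not align with sample rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def restrict(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column restriction to the given feature names, in their order."""
        index = {n: i for i, n in enumerate(self.feature_names)}
        try:
            cols = [index[n] for n in names]
        except KeyError as exc:
            raise KeyError(f"feature {exc.args[0]!r} not present in matrix") from None
        return FeatureMatrix(
            sample_ids=list(self.sample_ids),
            feature_names=list(names),
            values=self.values[:, cols],
            labels=None if self.labels is None else self.labels.copy(),
        )

    def subset_rows(self, rows: Sequence[int]) -> "FeatureMatrix":
        rows = list(rows)
        return FeatureMatrix(
            sample_ids=[self.sample_ids[r] for r in rows],
            feature_names=list(self.feature_names),
            values=self.values[rows],
            labels=None if self.labels is None else self.labels[rows],
        )


def count_kmers(reads: ReadSet, k: int) -> KmerCountTable:
    """Count every overlapping length-k window over all reads of a sample.

    Windows containing any non-A/C/G/T letter are skipped; windows never
    span read boundaries.  If no read is long enough the table is empty
    (total 0) and a warning is logged.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    codes = _encode_reads(reads)
    counts = _count_codes(codes, k)
    if counts.sum() == 0:
        logger.warning(
            "sample %r: no countable %d-mers (reads shorter than k or all-ambiguous)",
            reads.sample_id,
            k,
        )
    return KmerCountTable(k=k, counts=counts)


def composition_vector(table: KmerCountTable) -> CompositionVector:
    """Occurrence frequencies count/total over all 4^k k-mers."""
    total = table.total
    if total == 0:
        raise ValueError(f"no countable {table.k}-mers in sample")
    return CompositionVector(k=table.k, values=table.counts / total)


@lru_cache(maxsize=None)
def composition_feature_names(k: int) -> list[str]:
    return [f"C:{s}" for s in _kmer_strings(k)]


def ico_dimension(k: int) -> int:
    """Length of the ICO vector: (k-1)*4^k + sum_{m=1}^{k-1} 4^m."""
    return (k - 1) * 4 ** k + sum(4 ** m for m in range(1, k))


@lru_cache(maxsize=None)
def ico_feature_names(k: int) -> list[str]:
    """Canonical component names, block order m = 1..k-1, lexicographic
    within blocks: ``F:<m>:<i>:<j>`` then ``I:<m>:<i>``."""
    names: list[str] = []
    for m in range(1, k):
        n = k - m
        i_strs = _kmer_strings(m)
        j_strs = _kmer_strings(n)
        names.extend(f"F:{m}:{i}:{j}" for i in i_strs for j in j_strs)
        names.extend(f"I:{m}:{i}" for i in i_strs)
    return names


def _ico_from_tables(
    count_by_len: dict[int, np.ndarray], k: int, pseudocount: float = 0.0
) -> np.ndarray:
    blocks: list[np.ndarray] = []
    c_k = count_by_len[k].astype(np.float64)
    if pseudocount:
        c_k = c_k + pseudocount
    total_k = c_k.sum()
    for m in range(1, k):
        n = k - m
        c_m = count_by_len[m].astype(np.float64)
        c_n = count_by_len[n].astype(np.float64)
        if pseudocount:
            c_m = c_m + pseudocount
            c_n = c_n + pseudocount
        p_i = c_m / c_m.sum() if c_m.sum() > 0 else np.zeros_like(c_m)
        p_j = c_n / c_n.sum() if c_n.sum() > 0 else np.zeros_like(c_n)
        p_ij = (c_k / total_k).reshape(4 ** m, 4 ** n)

        denom = np.outer(p_i, p_j)
        active = (p_ij > 0) & (denom > 0)
        f = np.zeros_like(p_ij)
        f[active] = p_ij[active] / denom[active]

        # conditional p(j|i): row-normalized over k-mer counts with prefix i
        c_mat = c_k.reshape(4 ** m, 4 ** n)
        row_tot = c_mat.sum(axis=1, keepdims=True)
        p_cond = np.divide(
            c_mat, row_tot, out=np.zeros_like(c_mat), where=row_tot > 0
        )
        log_term = np.zeros_like(p_ij)
        log_term[active] = np.log2(f[active])
        i_block = (p_cond * log_term).sum(axis=1)

        blocks.append(f.ravel())
        blocks.append(i_block)
    return np.concatenate(blocks)


def ico_vector(reads: ReadSet, k: int, pseudocount: float = 0.0) -> IcoVector:
    """Compute the full ICO vector of a sample at oligonucleotide length k.

    Requires k >= 2 (a k-mer must admit at least one split) and at least
    one countable k-mer in the sample.
    """
    if k < 2:
        raise ValueError(f"ICO requires k >= 2 (no split exists for k={k})")
    codes = _encode_reads(reads)
    count_by_len = {length: _count_codes(codes, length) for length in range(1, k + 1)}
    if count_by_len[k].sum() == 0:
        raise ValueError(
            f"sample {reads.sample_id!r}: no countable {k}-mers; cannot build ICO vector"
        )
    values = _ico_from_tables(count_by_len, k, pseudocount=pseudocount)
    return IcoVector(k=k, values=values)


def minmax_normalize(v: np.ndarray) -> np.ndarray:
    """Within-vector min-max scaling v' = (v - min) / (max - min).

    Applied per sample (never per feature column).  A constant vector
    maps to all zeros by convention.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot normalize an empty vector")
    vmin = v.min()
    vmax = v.max()
    if vmax == vmin:
        return np.zeros_like(v)
    return (v - vmin) / (vmax - vmin)


def infer_extraction(feature_names: Sequence[str]) -> dict:
    """Recover feature type and k from canonical feature names.

    ``F:<m>:<i>:<j>`` / ``I:<m>:<i>`` imply ICO with k = m + |j| (from an
    F-name); ``C:<kmer>`` implies composition with k = |kmer|.
    """
    if not feature_names:
        raise ValueError("no feature names to infer from")
    first = feature_names[0]
    if first.startswith("C:"):
        return {"feature": "composition", "k": len(first[2:])}
    for name in feature_names:
        if name.startswith("F:"):
            _, m, i, j = name.split(":")
            return {"feature": "ico", "k": len(i) + len(j)}
        if name.startswith("I:"):
            continue
    raise ValueError(f"cannot infer extraction settings from names like {first!r}")


def encode_labels(
    labels: Sequence[str], positive_label: Optional[str] = None
) -> tuple[np.ndarray, str]:
    """Map two string labels to {+1, -1}.

    The label designated positive (typically the diseased class) maps to
    +1.  When not designated, the lexicographically later label is used
    and a notice is logged.
    """
    distinct = sorted(set(labels))
    if len(distinct) != 2:
        raise ValueError(f"expected exactly two label values, got {distinct!r}")
    if positive_label is None:
        positive_label = distinct[1]
        logger.info(
            "positive class not designated; using lexicographically later label %r as +1",
            positive_label,
        )
    elif positive_label not in distinct:
        raise ValueError(f"positive label {positive_label!r} not among {distinct!r}")
    y = np.array([1 if lab == positive_label else -1 for lab in labels], dtype=np.int64)
    return y, positive_label


def build_feature_matrix(
    manifest: SampleManifest,
    k: int,
    feature: str = "ico",
    normalize: bool = True,
    pseudocount: float = 0.0,
    positive_label: Optional[str] = None,
) -> FeatureMatrix:
    """Extract the per-sample feature matrix for a whole manifest.

    One row per sample in manifest order; columns follow the canonical
    feature-name order.  With ``normalize`` (the default) every row is
    min-max scaled within itself; string labels, when present on every
    sample, are encoded to {+1, -1}.
    """
    if feature not in ("ico", "composition"):
        raise ValueError(f"feature must be 'ico' or 'composition', got {feature!r}")
    rows: list[np.ndarray] = []
    for entry in manifest:
        reads = read_sequences(entry.paths, sample_id=entry.sample_id)
        if feature == "ico":
            try:
                vec = ico_vector(reads, k, pseudocount=pseudocount).values
            except ValueError as exc:
                raise ValueError(f"sample {entry.sample_id!r}: {exc}") from None
        else:
            table = count_kmers(reads, k)
            if table.total == 0:
                raise ValueError(f"sample {entry.sample_id!r}: no countable {k}-mers")
            vec = composition_vector(table).values
        if normalize:
            vec = minmax_normalize(vec)
        rows.append(vec)
    names = ico_feature_names(k) if feature == "ico" else composition_feature_names(k)
    labels = None
    raw = manifest.labels
    if all(lab is not None for lab in raw) and len(manifest) > 0:
        labels, _ = encode_labels([str(lab) for lab in raw], positive_label)
    return FeatureMatrix(
        sample_ids=manifest.sample_ids,
        feature_names=list(names),
        values=np.vstack(rows) if rows else np.zeros((0, len(names))),
        labels=labels,
    )
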