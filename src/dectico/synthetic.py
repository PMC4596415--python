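"""Two-class synthetic metagenomic read collections.

Each "genome" is a stationary Markov chain of configurable order over
{A, C, G, T}; a community is a mixture of such taxa.  The two classes
share one pool of taxa but mix them in different proportions, so the
between-class signal is compositional (beta-diversity-like), controlled
by a single divergence parameter delta:

* delta = 0: identical mixing vectors (null datasets);
* delta = 1: disjoint taxon support (each class draws only from its own
  half of the taxon pool);
* in between, each class's mixing vector is the shared Dirichlet draw
  shrunk toward its class-exclusive restriction:
  ``pi_c = (1 - delta) * pi + delta * restrict_c(pi)``.

Reads are drawn independently: a taxon from the class mixture, an
initial context from the taxon chain's stationary distribution, then
Markov extension to the read length.  Everything is deterministic given
the master seed, and regeneration is byte-identical.  No sequencing
error model or quality strings are simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .seq_io import ManifestEntry, ReadSet, SampleManifest, write_manifest

__all__ = [
    "TaxonModel",
    "CommunityModel",
    "SimulatedDataset",
    "make_community",
    "simulate_sample",
    "simulate_dataset",
    "CLASS_LABELS",
]

BASES = "ACGT"
CLASS_LABELS = ("control", "disease")  # class 0, class 1


@dataclass
class TaxonModel:
    """An order-r Markov chain over {A,C,G,T} standing in for one genome."""

    id: str
    order: int
    initial: np.ndarray      # stationary distribution over 4^r contexts
    transitions: np.ndarray  # (4^r, 4) rows summing to 1

    def __post_init__(self):
        r = self.order
        if self.transitions.shape != (4 ** r, 4):
            raise ValueError(f"transitions must be (4^{r}, 4)")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if (self.transitions < 0).any() or (self.initial < 0).any():
            raise ValueError("probabilities must be non-negative")


@dataclass
class CommunityModel:
    """A taxon pool plus two class-specific mixing vectors."""

    taxa: list[TaxonModel]
    mixing: np.ndarray  # (2, n_taxa), rows sum to 1
    divergence: float
    seed: int

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def order(self) -> int:
        return self.taxa[0].order


@dataclass
class SimulatedDataset:
    """A generated dataset on disk plus its regeneration config."""

    outdir: Path
    manifest_path: Path
    manifest: SampleManifest
    config: dict = field(default_factory=dict)


def _stationary_context_distribution(transitions: np.ndarray, order: int) -> np.ndarray:
    """Stationary distribution of the induced context chain (context ->
    drop first base, append sampled base)."""
    n_ctx = 4 ** order
    P = np.zeros((n_ctx, n_ctx))
    for ctx in range(n_ctx):
        tail = ctx % (4 ** (order - 1)) if order > 1 else 0
        for b in range(4):
            P[ctx, tail * 4 + b] += transitions[ctx, b]
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def make_community(
    n_taxa: int,
    order: int = 2,
    divergence: float = 0.5,
    seed: int = 0,
    transition_concentration: float = 1.0,
    mixing_concentration: float = 2.0,
) -> CommunityModel:
    """Draw a random community model with the given between-class divergence.

    Transition rows are Dirichlet(``transition_concentration``) draws;
    the shared mixing vector is a Dirichlet(``mixing_concentration``)
    draw, tilted per class by ``divergence`` as described in the module
    docstring.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence must be in [0, 1], got {divergence}")
    rng = np.random.default_rng(seed)
    taxa: list[TaxonModel] = []
    for t in range(n_taxa):
        trans = rng.dirichlet(np.full(4, transition_concentration), size=4 ** order)
        init = _stationary_context_distribution(trans, order)
        taxa.append(
            TaxonModel(id=f"taxon{t}", order=order, initial=init, transitions=trans)
        )
    shared = rng.dirichlet(np.full(n_taxa, mixing_concentration))
    half = (n_taxa + 1) // 2
    mixing = np.zeros((2, n_taxa))
    for c, members in enumerate((np.arange(half), np.arange(half, n_taxa))):
        restricted = np.zeros(n_taxa)
        restricted[members] = shared[members]
        total = restricted.sum()
        if total == 0:  # degenerate draw; fall back to uniform over members
            restricted[members] = 1.0 / members.size
        else:
            restricted /= total
        mixing[c] = (1.0 - divergence) * shared + divergence * restricted
    return CommunityModel(taxa=taxa, mixing=mixing, divergence=divergence, seed=seed)


def _decode_reads(codes: np.ndarray) -> list[str]:
    byte_map = np.frombuffer(b"ACGT", dtype=np.uint8)
    byte_rows = byte_map[codes]
    return [bytes(row).decode("ascii") for row in byte_rows]


def simulate_sample(
    model: CommunityModel,
    class_index: int,
    n_reads: int,
    read_length: int,
    seed,
    sample_id: str = "sample",
    out_path: Optional[str | Path] = None,
) -> ReadSet:
    """Simulate one sample's reads; optionally write them as FASTA.

    Each read draws a taxon from the class's mixing vector, an initial
    context from that taxon's stationary distribution, and extends by
    the taxon's Markov chain to ``read_length``.  Deterministic given
    ``seed``; identical seeds give byte-identical FASTA output.
    """
    r = model.order
    if read_length <= r:
        raise ValueError(f"read_length must exceed the Markov order {r}")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if class_index not in (0, 1):
        raise ValueError("class_index must be 0 or 1")
    rng = np.random.default_rng(seed)
    taxa_idx = rng.choice(model.n_taxa, size=n_reads, p=model.mixing[class_index])
    codes = np.zeros((n_reads, read_length), dtype=np.int8)
    n_ctx = 4 ** r
    tail_mod = 4 ** (r - 1) if r > 1 else 1
    for t in range(model.n_taxa):
        rows = np.nonzero(taxa_idx == t)[0]
        if rows.size == 0:
            continue
        taxon = model.taxa[t]
        cum = np.cumsum(taxon.transitions, axis=1)
        ctx = rng.choice(n_ctx, size=rows.size, p=taxon.initial)
        # decode the initial context into the first r bases
        for pos in range(r):
            shift = 4 ** (r - 1 - pos)
            codes[rows, pos] = (ctx // shift) % 4
        for pos in range(r, read_length):
            u = rng.random(rows.size)
            nxt = (cum[ctx] < u[:, None]).sum(axis=1).astype(np.int64)
            codes[rows, pos] = nxt
            ctx = (ctx % tail_mod) * 4 + nxt
    sequences = _decode_reads(codes)
    reads = ReadSet(sample_id=sample_id, sequences=sequences)
    if out_path is not None:
        with open(out_path, "w") as fh:
            for i, seq in enumerate(sequences):
                fh.write(f">{sample_id}_read{i}\n{seq}\n")
    return reads


def simulate_dataset(
    model: CommunityModel,
    samples_per_class: int,
    n_reads: int,
    read_length: int,
    outdir: str | Path,
    seed: int = 0,
) -> SimulatedDataset:
    """Write a full two-class dataset: FASTA per sample, labeled manifest,
    and a config echo sufficient for exact regeneration.

    Per-sample seeds are derived from the master seed by counter, so any
    sample can be regenerated independently.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries: list[ManifestEntry] = []
    counter = 0
    for c, label in enumerate(CLASS_LABELS):
        for s in range(samples_per_class):
            sid = f"{label}_{s:03d}"
            fasta = outdir / f"{sid}.fasta"
            simulate_sample(
                model,
                class_index=c,
                n_reads=n_reads,
                read_length=read_length,
                seed=[seed, counter],
                sample_id=sid,
                out_path=fasta,
            )
            entries.append(ManifestEntry(sample_id=sid, paths=(fasta.name,), label=label))
            counter += 1
    # the TSV stores paths relative to the manifest (relocatable); the
    # returned in-memory manifest carries resolved paths
    manifest_path = outdir / "manifest.tsv"
    write_manifest(SampleManifest(entries=entries), manifest_path)
    manifest = SampleManifest(
        entries=[
            ManifestEntry(
                sample_id=e.sample_id,
                paths=tuple(str(outdir / p) for p in e.paths),
                label=e.label,
            )
            for e in entries
        ]
    )
    config = {
        "seed": seed,
        "samples_per_class": samples_per_class,
        "n_reads": n_reads,
        "read_length": read_length,
        "n_taxa": model.n_taxa,
        "order": model.order,
        "divergence": model.divergence,
        "model_seed": model.seed,
    }
    with open(outdir / "config.json", "w") as fh:
        json.dump(config, fh, indent=1)
    return SimulatedDataset(
        outdir=outdir, manifest_path=manifest_path, manifest=manifest, config=config
    )
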