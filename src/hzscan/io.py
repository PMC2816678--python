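"""Reading and writing the formats the pipeline touches.

Per-locus multiple alignments come in as FASTA with one record per diploid
individual; heterozygous positions are encoded with the two-fold IUPAC
ambiguity codes (R, Y, S, W, K, M).  Sample and locus metadata are
tab-separated tables.  All results leave as TSV plus a JSON run manifest.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, AlphabetError, EmptyInputError, MetadataError

#: Bases, two-fold ambiguity codes, gap and unknown.  Three- and four-fold
#: codes (B, D, H, V) cannot arise in a diploid consensus and are rejected.
ALLOWED_ALPHABET = frozenset("ACGTRYSWKM-N")

POPULATIONS = ("favorinus", "admixed", "emma")
SCORE_LEVELS = (0.0, 0.5, 1.0)
INTERVALS = ("D", "Cr", "unlinked")


@dataclass
class LocusAlignment:
    """Multiple alignment of diploid consensus sequences for one locus."""

    locus_name: str
    sequences: dict[str, str]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise EmptyInputError(f"{self.locus_name}: alignment has no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.locus_name}: unequal sequence lengths {sorted(lengths)}"
            )
        self.length = lengths.pop()
        for ind, seq in self.sequences.items():
            bad = set(seq) - ALLOWED_ALPHABET
            if bad:
                raise AlphabetError(
                    f"{self.locus_name}/{ind}: illegal characters {sorted(bad)}"
                )

    @property
    def individuals(self) -> list[str]:
        return list(self.sequences)


@dataclass
class SampleMeta:
    """One sampled individual: population label and wing-pattern scores.

    ``d_score``/``cr_score`` code the phenotype on each patterning axis as
    0.0 (favorinus-like), 0.5 (hybrid) or 1.0 (emma-like).
    ``cr_dominant_ambiguous`` marks individuals whose Cr genotype is hidden
    by dominance (emma-type on both axes), which forces ``cr_score = 0.5``.
    """

    individual_id: str
    population: str
    d_score: float
    cr_score: float
    cr_dominant_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise MetadataError(
                f"{self.individual_id}: unknown population {self.population!r}"
            )
        for name, score in (("d_score", self.d_score), ("cr_score", self.cr_score)):
            if score not in SCORE_LEVELS:
                raise MetadataError(
                    f"{self.individual_id}: {name}={score!r} not in {SCORE_LEVELS}"
                )
        if self.cr_dominant_ambiguous and self.cr_score != 0.5:
            raise MetadataError(
                f"{self.individual_id}: ambiguity flag requires cr_score=0.5"
            )


@dataclass
class LocusAnnotation:
    """Where a sequenced locus sits: interval and 1-based bp offset along it."""

    locus_name: str
    interval: str
    interval_position: int
    length: int

    def __post_init__(self) -> None:
        if self.interval not in INTERVALS:
            raise MetadataError(
                f"{self.locus_name}: unknown interval {self.interval!r}"
            )
        if self.interval_position < 1 or self.length < 1:
            raise MetadataError(f"{self.locus_name}: positions must be positive")


def read_locus_alignment(path: str | os.PathLike, locus_name: str | None = None) -> LocusAlignment:
    """Read one per-locus FASTA alignment; headers carry individual ids."""
    if locus_name is None:
        locus_name = os.path.splitext(os.path.basename(path))[0]
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise MetadataError(f"{locus_name}: duplicate individual id {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    return LocusAlignment(locus_name, sequences)


def write_locus_alignment(aln: LocusAlignment, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for ind, seq in aln.sequences.items():
            fh.write(f">{ind}\n{seq}\n")


SAMPLE_COLUMNS = ["individual", "population", "d_score", "cr_score", "cr_dominant_ambiguous"]


def read_sample_table(path: str | os.PathLike) -> list[SampleMeta]:
    """Read the sample metadata TSV (individual, population, scores)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty sample table") from exc
    missing = set(SAMPLE_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise MetadataError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise EmptyInputError(f"{path}: sample table has no rows")
    if "cr_dominant_ambiguous" not in df.columns:
        df["cr_dominant_ambiguous"] = False
    samples = [
        SampleMeta(
            individual_id=str(r.individual),
            population=str(r.population),
            d_score=float(r.d_score),
            cr_score=float(r.cr_score),
            cr_dominant_ambiguous=bool(r.cr_dominant_ambiguous),
        )
        for r in df.itertuples(index=False)
    ]
    ids = [s.individual_id for s in samples]
    if len(set(ids)) != len(ids):
        raise MetadataError(f"{path}: duplicate individual ids")
    return samples


def write_sample_table(samples: list[SampleMeta], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            (s.individual_id, s.population, s.d_score, s.cr_score, s.cr_dominant_ambiguous)
            for s in samples
        ],
        columns=SAMPLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


LOCUS_COLUMNS = ["locus", "interval", "interval_position", "length"]


def read_locus_table(path: str | os.PathLike) -> list[LocusAnnotation]:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty locus table") from exc
    missing = set(LOCUS_COLUMNS) - set(df.columns)
    if missing:
        raise MetadataError(f"{path}: missing columns {sorted(missing)}")
    annots = [
        LocusAnnotation(str(r.locus), str(r.interval), int(r.interval_position), int(r.length))
        for r in df.itertuples(index=False)
    ]
    names = [a.locus_name for a in annots]
    if len(set(names)) != len(names):
        raise MetadataError(f"{path}: duplicate locus names")
    return annots


def write_locus_table(annots: list[LocusAnnotation], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(a.locus_name, a.interval, a.interval_position, a.length) for a in annots],
        columns=LOCUS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | os.PathLike,
    manifest: dict | None = None,
) -> dict[str, str]:
    """Write result tables as TSV plus a JSON run manifest.

    Column order and float formatting are fixed so that reruns with the same
    seed produce byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    written: dict[str, str] = {}
    for name, df in tables.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")
        written[name] = path
    if manifest is not None:
        path = os.path.join(out_dir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        written["manifest"] = path
    return written
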