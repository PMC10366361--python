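"""Barcode extraction and counting from paired-end amplicon reads.

Amplicons carry a 48-bp variable barcode region embedded in constant
flanking sequence: on the forward mate the region starts after 20
constant bases, on the reverse mate after 79.  Reads are quality
filtered (mean Phred and minimum length), cropped to the variable
window with 0-based half-open coordinates, the reverse-mate window is
reverse-complemented into library orientation, and both windows are
matched against a whitelist of known barcode sequences.  Each read
pair contributes at most one count.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Arm label of the DMSO (vehicle) control sample.
ARM_DMSO = "dmso"
#: Arm label of the pre-treatment baseline sample.
ARM_INITIAL = "initial"
#: Prefix shared by the drug-selected replicate arms (replicate-A, -B, -C).
ARM_REPLICATE_PREFIX = "replicate-"
#: Prefix of longitudinal medium samples (medium-timepoint-1, -2, ...).
ARM_MEDIUM_PREFIX = "medium-timepoint-"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadStructure:
    """Coordinates and quality thresholds of the amplicon read layout.

    All coordinates are 0-based half-open; lengths in bases.  Defaults
    describe a 150-bp paired-end run in which the 48-bp variable region
    starts at base 20 of the forward mate and base 79 of the reverse mate.
    """

    fwd_headcrop: int = 20
    fwd_croplen: int = 48
    rev_headcrop: int = 79
    rev_croplen: int = 48
    min_read_len: int = 147
    min_mean_phred: float = 20.0

    def __post_init__(self) -> None:
        if min(self.fwd_croplen, self.rev_croplen, self.min_read_len) <= 0:
            raise ValueError("croplen and min_read_len must be positive")
        if self.fwd_headcrop < 0 or self.rev_headcrop < 0:
            raise ValueError("headcrop must be non-negative")
        if self.fwd_headcrop + self.fwd_croplen > self.min_read_len:
            raise ValueError("forward crop window exceeds min_read_len")
        if self.rev_headcrop + self.rev_croplen > self.min_read_len:
            raise ValueError("reverse crop window exceeds min_read_len")


class BarcodeLibraryError(ValueError):
    """Malformed or inconsistent barcode whitelist."""


@dataclass
class BarcodeLibrary:
    """Whitelist of known variable-region barcode sequences.

    ``ids`` and ``sequences`` are parallel; sequences are unique,
    upper-case ACGT strings of one common length.
    """

    ids: list[int]
    sequences: list[str]
    _seq_to_id: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise BarcodeLibraryError("ids and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise BarcodeLibraryError(f"sequences of mixed lengths: {sorted(lengths)}")
        self._seq_to_id = {}
        for bc_id, seq in zip(self.ids, self.sequences):
            if seq in self._seq_to_id:
                raise BarcodeLibraryError(f"duplicate barcode sequence: {seq}")
            self._seq_to_id[seq] = bc_id

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def barcode_length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def lookup(self, seq: str) -> int | None:
        """Exact whitelist match, or None."""
        return self._seq_to_id.get(seq)

    def lookup_hamming1(self, seq: str) -> int | None:
        """Nearest whitelist barcode within Hamming distance 1.

        Exact matches win; otherwise every single-base substitution is
        probed and a hit is returned only if all hits agree on one barcode.
        """
        hit = self._seq_to_id.get(seq)
        if hit is not None:
            return hit
        found: int | None = None
        for i, base in enumerate(seq):
            prefix, suffix = seq[:i], seq[i + 1 :]
            for alt in "ACGT":
                if alt == base:
                    continue
                cand = self._seq_to_id.get(prefix + alt + suffix)
                if cand is None:
                    continue
                if found is not None and cand != found:
                    return None  # no unique minimizer
                found = cand
        return found

    def save(self, path: str | Path) -> None:
        """Write as TSV ``barcode_id<TAB>sequence``."""
        with open(path, "w") as fh:
            for bc_id, seq in zip(self.ids, self.sequences):
                fh.write(f"{bc_id}\t{seq}\n")


def _validate_seq(seq: str, lineno: int) -> str:
    seq = seq.strip().upper()
    if not seq or set(seq) - set("ACGT"):
        raise BarcodeLibraryError(
            f"line {lineno}: barcode sequence must be non-empty ACGT, got {seq!r}"
        )
    return seq


def load_library(path: str | Path) -> BarcodeLibrary:
    """Load a barcode whitelist.

    Accepts either TSV (``barcode_id<TAB>sequence``) or headerless
    one-sequence-per-line text; IDs in the latter case are assigned 1..n
    in file order.  Duplicate sequences raise :class:`BarcodeLibraryError`.
    """
    ids: list[int] = []
    seqs: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                try:
                    bc_id = int(parts[0])
                except ValueError as exc:
                    raise BarcodeLibraryError(
                        f"line {lineno}: barcode_id must be an integer, got {parts[0]!r}"
                    ) from exc
                ids.append(bc_id)
                seqs.append(_validate_seq(parts[1], lineno))
            elif len(parts) == 1:
                ids.append(len(ids) + 1)
                seqs.append(_validate_seq(parts[0], lineno))
            else:
                raise BarcodeLibraryError(f"line {lineno}: expected 1 or 2 columns")
    if not ids:
        raise BarcodeLibraryError(f"empty barcode library: {path}")
    return BarcodeLibrary(ids=ids, sequences=seqs)


@dataclass
class CountMatrix:
    """Barcode-by-sample integer read counts with sample metadata.

    ``counts`` is a DataFrame indexed by barcode_id with one column per
    sample_id.  ``arms`` maps each sample to its arm label (``initial``,
    ``dmso``, ``replicate-A`` ..., or ``medium-timepoint-k``).
    ``total_reads`` is the number of input read pairs per sample;
    ``tallies`` holds matched/ambiguous/unmatched pair counts.
    """

    counts: pd.DataFrame
    arms: dict[str, str]
    total_reads: dict[str, int] = field(default_factory=dict)
    tallies: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.arms)
        if missing:
            raise ValueError(f"samples without arm labels: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_arm(self, prefix: str) -> list[str]:
        return [s for s in self.counts.columns if self.arms[s].startswith(prefix)]

    @property
    def replicate_samples(self) -> list[str]:
        return self.samples_in_arm(ARM_REPLICATE_PREFIX)

    @property
    def dmso_samples(self) -> list[str]:
        return [s for s in self.counts.columns if self.arms[s] == ARM_DMSO]

    def to_tsv(self, path: str | Path) -> None:
        """Write counts TSV plus a JSON sidecar of arms/totals/tallies."""
        path = Path(path)
        self.counts.rename_axis("barcode_id").to_csv(path, sep="\t")
        sidecar = {
            "arms": self.arms,
            "total_reads": self.total_reads,
            "tallies": self.tallies,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def from_tsv(cls, path: str | Path, arms: dict[str, str] | None = None) -> "CountMatrix":
        path = Path(path)
        counts = pd.read_csv(path, sep="\t", index_col="barcode_id")
        sidecar_path = path.with_suffix(path.suffix + ".json")
        total_reads: dict[str, int] = {}
        tallies: dict[str, dict[str, int]] = {}
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            arms = arms or sidecar.get("arms", {})
            total_reads = sidecar.get("total_reads", {})
            tallies = sidecar.get("tallies", {})
        if arms is None:
            raise ValueError(f"no arm metadata: provide `arms` or sidecar {sidecar_path}")
        return cls(counts=counts, arms=dict(arms), total_reads=total_reads, tallies=tallies)


def _mean_phred(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual)


def quality_pass(seq: str, qual: str, rs: ReadStructure) -> bool:
    """True iff the read is long enough and its mean Phred clears the floor.

    ``qual`` is the Phred+33 quality string of the read.
    """
    if len(seq) < rs.min_read_len:
        return False
    return _mean_phred(qual) >= rs.min_mean_phred


def extract_variable_region(
    mate1: str, mate2: str, rs: ReadStructure
) -> tuple[str, str] | None:
    """Crop both mates to the 48-bp variable window.

    Returns ``(fwd_seq, rev_seq)`` with the reverse-mate window
    reverse-complemented into library orientation, or None when either
    mate is too short to contain its window.
    """
    if len(mate1) < rs.fwd_headcrop + rs.fwd_croplen:
        return None
    if len(mate2) < rs.rev_headcrop + rs.rev_croplen:
        return None
    fwd = mate1[rs.fwd_headcrop : rs.fwd_headcrop + rs.fwd_croplen].upper()
    rev_window = mate2[rs.rev_headcrop : rs.rev_headcrop + rs.rev_croplen]
    return fwd, reverse_complement(rev_window).upper()


def match_and_count(
    regions: Iterable[tuple[str, str]],
    lib: BarcodeLibrary,
    max_mismatch: int = 0,
    sample_id: str = "sample",
    arm: str = "replicate-A",
) -> CountMatrix:
    """Count whitelist matches over a stream of extracted region pairs.

    A pair contributes exactly one count: when both mates match the same
    barcode, or only one mate matches, that barcode is counted; mates
    matching different barcodes are tallied as ambiguous; pairs with no
    match are tallied as unmatched.
    """
    if len(lib) == 0:
        raise ValueError("empty barcode library")
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    lookup = lib.lookup if max_mismatch == 0 else lib.lookup_hamming1
    counter: Counter[int] = Counter()
    matched = ambiguous = unmatched = 0
    for fwd, rev in regions:
        id1 = lookup(fwd)
        id2 = lookup(rev)
        if id1 is None and id2 is None:
            unmatched += 1
        elif id1 is not None and id2 is not None and id1 != id2:
            ambiguous += 1
        else:
            counter[id1 if id1 is not None else id2] += 1  # type: ignore[index]
            matched += 1
    total = matched + ambiguous + unmatched
    counts = pd.DataFrame(
        {sample_id: [counter.get(b, 0) for b in lib.ids]}, index=pd.Index(lib.ids, name="barcode_id")
    )
    return CountMatrix(
        counts=counts,
        arms={sample_id: arm},
        total_reads={sample_id: total},
        tallies={sample_id: {"matched": matched, "ambiguous": ambiguous, "unmatched": unmatched}},
    )


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_region_pairs(
    r1_path: str | Path, r2_path: str | Path, rs: ReadStructure
) -> Iterator[tuple[str, str]]:
    """Stream quality-passing, cropped region pairs from paired FASTQ files."""
    with _open_maybe_gzip(r1_path) as fh1, _open_maybe_gzip(r2_path) as fh2:
        for (_, seq1, q1), (_, seq2, q2) in zip(
            FastqGeneralIterator(fh1), FastqGeneralIterator(fh2), strict=True
        ):
            if not (quality_pass(seq1, q1, rs) and quality_pass(seq2, q2, rs)):
                continue
            pair = extract_variable_region(seq1, seq2, rs)
            if pair is not None:
                yield pair


def count_fastq_sample(
    r1_path: str | Path,
    r2_path: str | Path,
    lib: BarcodeLibrary,
    rs: ReadStructure | None = None,
    max_mismatch: int = 0,
    sample_id: str = "sample",
    arm: str = "replicate-A",
) -> CountMatrix:
    """Full per-sample pipeline: FASTQ pair -> quality filter -> crop -> count."""
    rs = rs or ReadStructure()
    return match_and_count(
        iter_region_pairs(r1_path, r2_path, rs),
        lib,
        max_mismatch=max_mismatch,
        sample_id=sample_id,
        arm=arm,
    )


def merge_count_matrices(parts: Sequence[CountMatrix]) -> CountMatrix:
    """Column-concatenate single-sample matrices sharing a barcode ID space."""
    if not parts:
        raise ValueError("no count matrices to merge")
    base_index = parts[0].counts.index
    for p in parts[1:]:
        if not p.counts.index.equals(base_index):
            raise ValueError("count matrices use inconsistent barcode libraries")
    counts = pd.concat([p.counts for p in parts], axis=1)
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample_id across merged matrices")
    arms: dict[str, str] = {}
    totals: dict[str, int] = {}
    tallies: dict[str, dict[str, int]] = {}
    for p in parts:
        arms.update(p.arms)
        totals.update(p.total_reads)
        tallies.update(p.tallies)
    return CountMatrix(counts=counts, arms=arms, total_reads=totals, tallies=tallies)


def filter_low_counts(cm: CountMatrix, min_count: int = 2) -> CountMatrix:
    """Drop barcodes below ``min_count`` in every drug replicate and the DMSO control.

    A barcode is retained iff its count reaches ``min_count`` in at least
    one drug-selected replicate sample or the DMSO control; other columns
    (initial, medium) do not rescue a barcode.  Idempotent.
    """
    relevant = cm.replicate_samples + cm.dmso_samples
    if not relevant:
        raise ValueError("count matrix has no replicate or DMSO samples to filter on")
    keep = (cm.counts[relevant] >= min_count).any(axis=1)
    return CountMatrix(
        counts=cm.counts.loc[keep].copy(),
        arms=dict(cm.arms),
        total_reads=dict(cm.total_reads),
        tallies={k: dict(v) for k, v in cm.tallies.items()},
    )
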