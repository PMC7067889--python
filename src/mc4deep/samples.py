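"""Reading, validating and filtering labelled fixed-length DNA windows.

A *sample* is one cytosine-centred window of fixed length (41 bp by
default) together with a binary label: positive windows carry a genuine
4mC (N4-methylcytosine) site at the central cytosine, negative windows
have an unmodified central cytosine.  Samples may carry an optional
``modqv`` quality score, the SMRT-kinetics modification quality value.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DEFAULT_LENGTH = 41
ALPHABET = frozenset("ACGT")

_POSITIVE_TOKENS = {"1", "pos", "positive", "+"}
_NEGATIVE_TOKENS = {"0", "neg", "negative", "-"}


@dataclass(frozen=True)
class DnaSample:
    """One labelled DNA window.

    Attributes
    ----------
    id : str
        Record identifier (FASTA header up to the first whitespace,
        with any ``|pos`` / ``|neg`` label tag stripped).
    sequence : str
        Upper-case sequence over {A, C, G, T}.
    label : int
        1 for a 4mC-positive window, 0 for negative.
    modqv : float or None
        Optional modification quality value (non-negative).
    """

    id: str
    sequence: str
    label: int
    modqv: float | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


def _parse_label(token: str, context: str) -> int:
    t = token.strip().lower()
    if t in _POSITIVE_TOKENS:
        return 1
    if t in _NEGATIVE_TOKENS:
        return 0
    raise ValueError(f"unrecognised label {token!r} for {context}")


def normalize_sequence(raw: str, record_id: str) -> str:
    """Upper-case and map U->T; any residue outside {A,C,G,T} is an error."""
    seq = raw.upper().replace("U", "T")
    for pos, base in enumerate(seq, start=1):
        if base not in ALPHABET:
            raise ValueError(
                f"record {record_id!r}: non-ACGT residue {base!r} at position {pos}"
            )
    return seq


def _check_centre(sample: DnaSample, mode: Literal["fail", "warn", "off"]) -> None:
    if mode == "off":
        return
    centre = (sample.length + 1) // 2  # 1-based centre of an odd-length window
    base = sample.sequence[centre - 1]
    if base != "C":
        msg = (
            f"record {sample.id!r}: centre position {centre} is {base!r}, expected 'C'"
        )
        if mode == "fail":
            raise ValueError(msg)
        logger.warning(msg)


def read_labels_tsv(path: str | Path) -> dict[str, int]:
    """Read a sidecar ``id<TAB>label`` table (label in {1,0,pos,neg})."""
    labels: dict[str, int] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {line_no}: expected 'id<TAB>label'")
        labels[parts[0]] = _parse_label(parts[1], f"id {parts[0]!r}")
    return labels


def read_modqv_tsv(path: str | Path) -> dict[str, float]:
    """Read a sidecar ``id<TAB>modqv`` table of quality scores."""
    scores: dict[str, float] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {line_no}: expected 'id<TAB>modqv'")
        value = float(parts[1])
        if value < 0:
            raise ValueError(f"{path}: line {line_no}: negative modqv {value}")
        scores[parts[0]] = value
    return scores


def read_samples(
    fasta_path: str | Path,
    labels_source: str | Path | dict[str, int] | None = None,
    *,
    length: int = DEFAULT_LENGTH,
    centre_check: Literal["fail", "warn", "off"] = "fail",
    modqv_source: str | Path | dict[str, float] | None = None,
) -> list[DnaSample]:
    """Read labelled windows from FASTA, in file order.

    Labels come either from a header tag (``>id|pos`` / ``>id|neg`` /
    ``>id|1`` / ``>id|0``) or from ``labels_source`` (a TSV path or an
    id->label mapping).  Every record must resolve to a label.  Records
    whose normalized length differs from ``length`` are rejected.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(str(fasta_path))

    label_map: dict[str, int] | None
    if labels_source is None:
        label_map = None
    elif isinstance(labels_source, dict):
        label_map = dict(labels_source)
    else:
        label_map = read_labels_tsv(labels_source)

    modqv_map: dict[str, float] = {}
    if isinstance(modqv_source, dict):
        modqv_map = dict(modqv_source)
    elif modqv_source is not None:
        modqv_map = read_modqv_tsv(modqv_source)

    samples: list[DnaSample] = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        header_id = record.id
        rec_id, label = header_id, None
        if "|" in header_id:
            stem, _, tag = header_id.rpartition("|")
            try:
                label = _parse_label(tag, f"record {header_id!r}")
                rec_id = stem
            except ValueError:
                label = None  # pipe belongs to the id, not a label tag
        if label_map is not None:
            lookup_id = rec_id if rec_id in label_map else header_id
            if lookup_id not in label_map:
                raise ValueError(f"no label for record {header_id!r}")
            label = label_map[lookup_id]
            rec_id = lookup_id
        if label is None:
            raise ValueError(
                f"no label for record {header_id!r}: tag the header with |pos / |neg "
                "or provide a labels TSV"
            )
        seq = normalize_sequence(str(record.seq), rec_id)
        if len(seq) != length:
            raise ValueError(
                f"record {rec_id!r}: length {len(seq)} != expected {length}"
            )
        sample = DnaSample(
            id=rec_id, sequence=seq, label=label, modqv=modqv_map.get(rec_id)
        )
        _check_centre(sample, centre_check)
        samples.append(sample)
    return samples


def write_samples(
    samples: Sequence[DnaSample],
    fasta_path: str | Path,
    labels_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
) -> None:
    """Write samples back out as FASTA plus optional label/modqv sidecars."""
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description="") for s in samples
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if labels_path is not None:
        lines = [f"{s.id}\t{s.label}" for s in samples]
        Path(labels_path).write_text("\n".join(lines) + ("\n" if lines else ""))
    if metadata_path is not None:
        lines = [f"{s.id}\t{s.modqv:g}" for s in samples if s.modqv is not None]
        Path(metadata_path).write_text("\n".join(lines) + ("\n" if lines else ""))


def filter_by_modqv(
    samples: Sequence[DnaSample],
    threshold: float = 30.0,
    mode: Literal["drop_above", "drop_below"] = "drop_above",
) -> list[DnaSample]:
    """Quality-filter on the modQV score; samples without a score pass.

    The default (threshold 30, ``drop_above``) removes samples whose
    modQV exceeds 30 and keeps scores equal to the threshold.  The
    inverted rule (``drop_below``, keeping confidently modified calls)
    is available because the literal published rule and the stated
    meaning of the threshold point in opposite directions.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    if mode not in ("drop_above", "drop_below"):
        raise ValueError(f"unknown mode {mode!r}")
    kept: list[DnaSample] = []
    for s in samples:
        if s.modqv is None:
            kept.append(s)
        elif mode == "drop_above" and s.modqv <= threshold:
            kept.append(s)
        elif mode == "drop_below" and s.modqv >= threshold:
            kept.append(s)
    logger.info(
        "modqv filter (%s %g): kept %d of %d", mode, threshold, len(kept), len(samples)
    )
    return kept


def dedup_exact(samples: Sequence[DnaSample]) -> list[DnaSample]:
    """Remove exact duplicate sequences, keeping the first occurrence.

    A weaker stand-in for similarity clustering (see :func:`dedup_cdhit`):
    only byte-identical sequences are collapsed.
    """
    seen: set[str] = set()
    kept: list[DnaSample] = []
    for s in samples:
        if s.sequence not in seen:
            seen.add(s.sequence)
            kept.append(s)
    removed = len(samples) - len(kept)
    if removed:
        logger.info("dedup_exact: removed %d exact duplicates", removed)
    return kept


def dedup_cdhit(
    samples: Sequence[DnaSample],
    identity: float = 0.8,
    cdhit_binary: str = "cd-hit-est",
) -> list[DnaSample]:
    """Cluster near-identical sequences with an external CD-HIT binary.

    Shells out to ``cdhit_binary`` (``cd-hit-est``) at the given identity
    cutoff and keeps each cluster representative.  Raises
    ``FileNotFoundError`` when the binary is not on PATH; callers that
    want a built-in fallback should use :func:`dedup_exact`, which is
    logged as the weaker exact-match rule.
    """
    if shutil.which(cdhit_binary) is None:
        raise FileNotFoundError(
            f"CD-HIT binary {cdhit_binary!r} not found on PATH; "
            "use dedup_exact() for the built-in exact-duplicate fallback"
        )
    by_id = {s.id: s for s in samples}
    with tempfile.TemporaryDirectory() as tmp:
        fasta_in = Path(tmp) / "in.fasta"
        fasta_out = Path(tmp) / "out.fasta"
        write_samples(list(samples), fasta_in)
        subprocess.run(
            [cdhit_binary, "-i", str(fasta_in), "-o", str(fasta_out),
             "-c", str(identity), "-n", "5"],
            check=True,
            capture_output=True,
        )
        kept_ids = [rec.id for rec in SeqIO.parse(str(fasta_out), "fasta")]
    kept = [by_id[i] for i in kept_ids if i in by_id]
    logger.info("dedup_cdhit: kept %d of %d at %.0f%% identity",
                len(kept), len(samples), 100 * identity)
    return kept


def with_modqv(sample: DnaSample, modqv: float | None) -> DnaSample:
    return replace(sample, modqv=modqv)


def labels_array(samples: Iterable[DnaSample]):
    import numpy as np

    return np.asarray([s.label for s in samples], dtype=int)
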