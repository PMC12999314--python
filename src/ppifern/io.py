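"""Readers and writers for every external representation the pipeline touches.

Covers FASTA protein sequences (via Biopython), the PSI-BLAST ASCII PSSM
dialect (``-out_ascii_pssm``), tab-separated interaction pair tables,
feature tables, JSON metrics reports and the versioned JSON model container.

All text I/O is UTF-8.  TSV files use literal tab separators and ``#``
comment lines are ignored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical residue-column ordering (the PSI-BLAST header order).  Every
#: parsed PSSM is remapped to this ordering so that feature indices are
#: comparable across files regardless of the column order a file declares.
CANONICAL_ALPHABET = tuple("ARNDCQEGHILKMFPSTWYV")

#: Residue letters tolerated in input sequences: the 20 standard amino
#: acids plus common ambiguity/non-standard codes.
TOLERATED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" "XBZU")

SCHEMA_VERSION = 1


class ParseError(ValueError):
    """Raised when an input file violates its expected dialect."""


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence (FASTA id = header token before whitespace)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        for ch in self.sequence:
            if ch not in TOLERATED_RESIDUES:
                raise ParseError(
                    f"protein {self.id!r}: residue {ch!r} outside the tolerated alphabet"
                )


@dataclass(frozen=True)
class PSSMatrix:
    """An L x 20 position-specific scoring matrix for one protein.

    ``scores[t, j]`` is the log-odds score of residue ``CANONICAL_ALPHABET[j]``
    at sequence position ``t``.
    """

    protein_id: str
    scores: np.ndarray
    residue_column_order: tuple[str, ...] = CANONICAL_ALPHABET

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != 20 or scores.shape[0] < 1:
            raise ValueError(
                f"PSSM for {self.protein_id!r}: expected (L, 20) with L >= 1, "
                f"got {scores.shape}"
            )
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class PairRow:
    id_a: str
    id_b: str
    label: int


@dataclass
class PairTable:
    """Rows of (protein id A, protein id B, binary interaction label)."""

    rows: list[PairRow]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.rows], dtype=int)

    def protein_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.id_a)
            seen.setdefault(r.id_b)
        return list(seen)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`.

    One record per ``>`` header, multi-line sequences concatenated, file
    order preserved.  Residues outside the tolerated alphabet raise
    :class:`ParseError` naming the record and the offending character.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(seq_records, fh, "fasta")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def _is_residue_row(tokens: list[str]) -> bool:
    if len(tokens) < 22:
        return False
    if not tokens[0].isdigit():
        return False
    return len(tokens[1]) == 1 and tokens[1].isalpha()


def parse_ascii_pssm(path: str | Path, protein_id: str | None = None) -> PSSMatrix:
    """Parse a PSI-BLAST ASCII PSSM file into a :class:`PSSMatrix`.

    Accepts both the 40-column variant (log-odds block followed by the
    weighted-percentage block, optionally two trailing per-row statistics)
    and the minimal 20-column variant; in either case the FIRST 20 numeric
    columns (the log-odds block) are returned.  Columns are remapped from
    the file's own header alphabet to :data:`CANONICAL_ALPHABET`.

    The footer statistics block and trailing blank lines are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if protein_id is None:
        protein_id = path.stem

    header_alphabet: list[str] | None = None
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if header_alphabet is None:
                # Header: a run of >= 20 single-letter tokens (40 in the
                # two-block dialect; the first 20 name the log-odds columns).
                letters = [t for t in tokens if len(t) == 1 and t.isalpha()]
                if len(letters) >= 20 and len(letters) == len(tokens):
                    header_alphabet = letters[:20]
                continue
            if _is_residue_row(tokens):
                numeric = tokens[2:]
                try:
                    values = [float(v) for v in numeric]
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score: {exc}")
                if len(values) not in (20, 40, 42):
                    raise ParseError(
                        f"{path}:{lineno}: expected 20 or 40(+2) numeric columns, "
                        f"got {len(values)}"
                    )
                rows.append(values[:20])
            elif rows and tokens and tokens[0].isdigit():
                # Started like a residue row but malformed (e.g. truncated).
                raise ParseError(
                    f"{path}:{lineno}: malformed residue row "
                    f"({len(tokens)} fields)"
                )
            elif rows:
                # First non-residue line after the body: footer begins.
                break
    if header_alphabet is None:
        raise ParseError(f"{path}: no PSSM header line found")
    if not rows:
        raise ParseError(f"{path}: PSSM body is empty")

    scores = np.asarray(rows, dtype=float)
    order = [header_alphabet.index(a) for a in CANONICAL_ALPHABET]
    if sorted(header_alphabet) != sorted(CANONICAL_ALPHABET):
        raise ParseError(
            f"{path}: header alphabet {header_alphabet} is not a permutation "
            f"of the 20 standard residues"
        )
    return PSSMatrix(protein_id=protein_id, scores=scores[:, order])


def write_ascii_pssm(
    pssm: PSSMatrix, sequence: str | None, path: str | Path
) -> None:
    """Write a PSSM in the PSI-BLAST ASCII dialect (40-column variant).

    The weighted-percentage block is filled with zeros; the two trailing
    per-row statistics are written as 0.00, mirroring what the parser
    ignores.  ``sequence`` supplies the residue letters of column two and
    defaults to all ``A`` when absent.
    """
    L = pssm.length
    if sequence is None:
        sequence = "A" * L
    if len(sequence) != L:
        raise ValueError("sequence length does not match PSSM row count")
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            "
        + "  ".join(CANONICAL_ALPHABET)
        + "   "
        + "  ".join(CANONICAL_ALPHABET),
    ]
    for t in range(L):
        scores = " ".join(f"{int(round(v)):4d}" for v in pssm.scores[t])
        pct = " ".join("   0" for _ in range(20))
        lines.append(f"{t + 1:5d} {sequence[t]} {scores} {pct}  0.00 0.00")
    lines += ["", "                      K         Lambda", ""]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_pssm_directory(
    directory: str | Path,
    ids: Iterable[str] | None = None,
    manifest: Mapping[str, str] | None = None,
) -> dict[str, PSSMatrix]:
    """Load PSSM files matched to protein ids by filename stem.

    ``manifest`` (id -> filename) overrides the stem-based linkage.
    When ``ids`` is given, only those ids are loaded and all must resolve.
    """
    directory = Path(directory)
    available = {p.stem: p for p in sorted(directory.glob("*.pssm"))}
    available.update({p.stem: p for p in sorted(directory.glob("*.txt"))})
    if manifest:
        for pid, fname in manifest.items():
            available[pid] = directory / fname
    wanted = list(ids) if ids is not None else list(available)
    missing = [pid for pid in wanted if pid not in available]
    if missing:
        raise KeyError(f"no PSSM file for protein ids: {sorted(missing)}")
    return {pid: parse_ascii_pssm(available[pid], protein_id=pid) for pid in wanted}


# ---------------------------------------------------------------------------
# Pair tables


def _parse_label(token: str, where: str) -> int:
    if token in ("0", "1"):
        return int(token)
    try:
        value = float(token)
    except ValueError:
        raise ParseError(f"{where}: label {token!r} is not binary")
    if value in (0.0, 1.0):
        return int(value)
    raise ParseError(f"{where}: label {token!r} outside {{0, 1}}")


def read_pair_table(path: str | Path) -> PairTable:
    """Read a TSV of (id_a, id_b, label) rows.

    A header row is auto-detected by a non-numeric third field.  Labels are
    coerced to {0, 1}; anything else is an error.  Exact duplicate rows are
    kept with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[PairRow] = []
    seen: set[tuple[str, str, int]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            if not rows and lineno == _first_content_line(path):
                try:
                    float(fields[2])
                except ValueError:
                    continue  # header row
            row = PairRow(
                id_a=fields[0].strip(),
                id_b=fields[1].strip(),
                label=_parse_label(fields[2].strip(), f"{path}:{lineno}"),
            )
            key = (row.id_a, row.id_b, row.label)
            if key in seen:
                logger.warning("%s:%d: duplicate pair row %s (kept)", path, lineno, key)
            seen.add(key)
            rows.append(row)
    return PairTable(rows=rows)


def _first_content_line(path: Path) -> int:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() and not line.lstrip().startswith("#"):
                return lineno
    return -1


def write_pair_table(table: PairTable, path: str | Path, header: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("id_a\tid_b\tlabel\n")
        for r in table.rows:
            fh.write(f"{r.id_a}\t{r.id_b}\t{r.label}\n")


# ---------------------------------------------------------------------------
# Feature tables


def write_feature_table(
    pair_ids: Sequence[tuple[str, str]],
    values: np.ndarray,
    path: str | Path,
    labels: Sequence[int] | None = None,
) -> None:
    """Write pair features as TSV: id columns, optional label, f0001..fNNNN."""
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    cols = ["id_a", "id_b"] + (["label"] if labels is not None else [])
    cols += [f"f{i + 1:04d}" for i in range(d)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for i in range(n):
            fields = [pair_ids[i][0], pair_ids[i][1]]
            if labels is not None:
                fields.append(str(int(labels[i])))
            fields += [repr(float(v)) for v in values[i]]
            fh.write("\t".join(fields) + "\n")


def read_feature_table(
    path: str | Path,
) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray | None]:
    """Read a feature TSV back into (pair ids, value matrix, labels or None)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        has_label = "label" in header[:3]
        skip = 3 if has_label else 2
        ids: list[tuple[str, str]] = []
        labels: list[int] = []
        values: list[list[float]] = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            ids.append((fields[0], fields[1]))
            if has_label:
                labels.append(int(fields[2]))
            values.append([float(v) for v in fields[skip:]])
    return ids, np.asarray(values, dtype=float), (
        np.asarray(labels, dtype=int) if has_label else None
    )


# ---------------------------------------------------------------------------
# Model bundle (versioned JSON container)


@dataclass
class ModelBundle:
    """Everything needed to reproduce predictions: SDAE (optional), ferns,
    and the featurization settings used at training time."""

    ferns: "object"
    sdae: "object | None" = None
    featurization_settings: "object | None" = None
    schema_version: int = SCHEMA_VERSION
    extra: dict = field(default_factory=dict)


def save_model(bundle: ModelBundle, path: str | Path) -> None:
    """Serialize a bundle as canonical JSON (sorted keys, repr-exact floats)."""
    from .featurize import FeaturizationSettings
    from .ferns import FernsModel
    from .sdae import SDAEModel

    payload = {
        "schema_version": bundle.schema_version,
        "ferns": bundle.ferns.to_dict() if bundle.ferns is not None else None,
        "sdae": bundle.sdae.to_dict() if bundle.sdae is not None else None,
        "featurization_settings": (
            bundle.featurization_settings.to_dict()
            if bundle.featurization_settings is not None
            else None
        ),
        "extra": bundle.extra,
    }
    text = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    Path(path).write_text(text, encoding="utf-8")


def load_model(path: str | Path) -> ModelBundle:
    from .featurize import FeaturizationSettings
    from .ferns import FernsModel
    from .sdae import SDAEModel

    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ParseError(f"{path}: not a valid model bundle: {exc}")
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise ParseError(f"{path}: not a model bundle (missing schema_version)")
    version = payload["schema_version"]
    if version != SCHEMA_VERSION:
        raise ParseError(
            f"{path}: unsupported schema_version {version} "
            f"(this build reads version {SCHEMA_VERSION})"
        )
    return ModelBundle(
        schema_version=version,
        ferns=FernsModel.from_dict(payload["ferns"]) if payload["ferns"] else None,
        sdae=SDAEModel.from_dict(payload["sdae"]) if payload.get("sdae") else None,
        featurization_settings=(
            FeaturizationSettings.from_dict(payload["featurization_settings"])
            if payload.get("featurization_settings")
            else None
        ),
        extra=payload.get("extra", {}),
    )


def write_metrics_json(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_jsonify),
        encoding="utf-8",
    )


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
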