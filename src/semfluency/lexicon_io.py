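"""Transcript, lexicon and cohort I/O.

A cohort is a list of per-participant transcripts from a timed category-fluency
task: the ordered raw word productions, the diagnostic group (PSP-RS, PD or
HC), demographic covariates, daily medication doses and optional clinical
scores.  Category membership and word identity are defined by a
:class:`CategoryLexicon` — a canonical in-category vocabulary plus a
variant -> canonical synonym map — supplied as data, never baked into code.

File formats
------------
Cohort CSV: columns ``participant_id, group, tokens, age, education`` then any
number of ``med_<drug>`` (mg/day) and ``clin_<score>`` columns.  Tokens are
pipe-separated inside the cell, production order preserved; the record
separator defaults to ``;`` because free-text tokens may contain commas.

Cohort JSON: a list of objects mirroring :class:`Transcript` fields.

Lexicon CSV: two columns ``variant,canonical``; rows with variant == canonical
declare canonical members, all other rows are synonym mappings.  File order of
the canonical rows is meaningful to the simulator (frequency rank).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Group",
    "Transcript",
    "CategoryLexicon",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "read_lexicon",
    "write_lexicon",
    "default_animal_lexicon",
    "normalize_token",
    "read_scores",
    "write_scores",
    "SchemaError",
]


class SchemaError(ValueError):
    """A file does not match the documented cohort/lexicon schema."""


class Group(str, Enum):
    """Diagnostic group label."""

    PSP_RS = "PSP_RS"
    PD = "PD"
    HC = "HC"

    @classmethod
    def parse(cls, raw: str) -> "Group":
        try:
            return cls(str(raw).strip())
        except ValueError:
            raise SchemaError(
                f"unknown group label {raw!r}; expected one of "
                f"{[g.value for g in cls]}"
            ) from None


@dataclass
class Transcript:
    """One participant's ordered productions plus metadata.

    ``tokens`` preserves transcription order exactly, duplicates included; an
    empty list is legal (a participant who produced nothing).  ``meds`` maps
    drug name to daily dose in mg/day; ``clinical`` holds any extra numeric
    scores (MoCA, H&Y, ...).
    """

    participant_id: str
    group: Group
    tokens: list[str]
    age: int = 0
    education: int = 0
    meds: dict[str, float] = field(default_factory=dict)
    clinical: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        if self.age < 0 or self.education < 0:
            raise SchemaError(
                f"{self.participant_id}: age/education must be >= 0"
            )
        for drug, dose in self.meds.items():
            if dose < 0:
                raise SchemaError(
                    f"{self.participant_id}: negative dose for {drug}"
                )


@dataclass
class CategoryLexicon:
    """Canonical in-category vocabulary plus synonym normalization map."""

    canonical: list[str]
    synonym_map: dict[str, str] = field(default_factory=dict)
    category_name: str = "animals"

    def __post_init__(self) -> None:
        self._canon_set = set(self.canonical)
        if len(self._canon_set) != len(self.canonical):
            raise SchemaError("duplicate canonical lexicon entries")
        for variant, canon in self.synonym_map.items():
            if canon not in self._canon_set:
                raise SchemaError(
                    f"synonym target {canon!r} (for {variant!r}) is not canonical"
                )
            if variant in self._canon_set:
                raise SchemaError(
                    f"variant {variant!r} is itself canonical but maps to {canon!r}"
                )

    def __contains__(self, word: str) -> bool:
        return word in self._canon_set

    def __len__(self) -> int:
        return len(self.canonical)


@dataclass
class Cohort:
    """All transcripts of one study plus free-text provenance."""

    transcripts: list[Transcript]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.transcripts:
            if t.participant_id in seen:
                raise SchemaError(
                    f"duplicate participant_id {t.participant_id!r}"
                )
            seen.add(t.participant_id)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)


_WS = re.compile(r"\s+")


def normalize_token(raw: str, lexicon: CategoryLexicon) -> tuple[str, bool]:
    """Normalize a raw token and resolve category membership.

    Lowercases, trims, collapses internal whitespace, then maps through the
    lexicon's synonym table.  Returns ``(canonical_form, in_category)``; a
    token neither canonical nor a known variant comes back unchanged (after
    normalization) with ``in_category=False``.  Total on strings — never
    raises.
    """
    token = _WS.sub(" ", str(raw).strip().lower())
    token = lexicon.synonym_map.get(token, token)
    return token, token in lexicon


# ---------------------------------------------------------------------------
# Lexicon I/O


def read_lexicon(path: str | Path, category_name: str = "animals") -> CategoryLexicon:
    """Read a two-column ``variant,canonical`` lexicon CSV."""
    canonical: list[str] = []
    synonyms: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        header = fh.readline().strip().lower().replace(" ", "")
        if header != "variant,canonical":
            raise SchemaError(
                f"{path}: expected header 'variant,canonical', got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise SchemaError(f"{path}:{lineno}: expected 2 columns")
            variant = _WS.sub(" ", parts[0].strip().lower())
            canon = _WS.sub(" ", parts[1].strip().lower())
            if variant == canon:
                canonical.append(canon)
            else:
                synonyms[variant] = canon
    return CategoryLexicon(canonical, synonyms, category_name)


def write_lexicon(lexicon: CategoryLexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("variant,canonical\n")
        for canon in lexicon.canonical:
            fh.write(f"{canon},{canon}\n")
        for variant, canon in lexicon.synonym_map.items():
            fh.write(f"{variant},{canon}\n")


def default_animal_lexicon() -> CategoryLexicon:
    """The packaged 200-word animal lexicon (file order = frequency rank)."""
    ref = resources.files("semfluency.data") / "animals.csv"
    with resources.as_file(ref) as path:
        return read_lexicon(path, "animals")


# ---------------------------------------------------------------------------
# Cohort I/O

_BASE_COLUMNS = ["participant_id", "group", "tokens", "age", "education"]
TOKEN_SEP = "|"


def _transcript_to_record(t: Transcript) -> dict:
    return {
        "participant_id": t.participant_id,
        "group": t.group.value,
        "tokens": list(t.tokens),
        "age": t.age,
        "education": t.education,
        "meds": dict(t.meds),
        "clinical": dict(t.clinical),
    }


def _record_to_transcript(rec: Mapping, where: str) -> Transcript:
    try:
        tokens = rec["tokens"]
        if isinstance(tokens, str):  # defensive: JSON written by hand
            tokens = [tok for tok in tokens.split(TOKEN_SEP) if tok != ""]
        return Transcript(
            participant_id=str(rec["participant_id"]),
            group=Group.parse(rec["group"]),
            tokens=[str(tok) for tok in tokens],
            age=int(rec.get("age", 0)),
            education=int(rec.get("education", 0)),
            meds={k: float(v) for k, v in dict(rec.get("meds", {})).items()},
            clinical={k: float(v) for k, v in dict(rec.get("clinical", {})).items()},
        )
    except KeyError as exc:
        raise SchemaError(f"{where}: missing field {exc}") from None


def read_cohort(path: str | Path, format: str | None = None, sep: str = ";") -> Cohort:
    """Read a cohort from CSV or JSON (format inferred from suffix if omitted)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        records = payload["transcripts"] if isinstance(payload, dict) else payload
        provenance = payload.get("provenance", {}) if isinstance(payload, dict) else {}
        transcripts = [
            _record_to_transcript(rec, f"{path} record {i}")
            for i, rec in enumerate(records)
        ]
        return Cohort(transcripts, dict(provenance))
    if format != "csv":
        raise ValueError(f"unknown cohort format {format!r}")

    transcripts = []
    with open(path, newline="", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise SchemaError(f"{path}: empty file")
        header = header_line.split(sep)
        missing = [c for c in _BASE_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        idx = {c: i for i, c in enumerate(header)}
        med_cols = [c for c in header if c.startswith("med_")]
        clin_cols = [c for c in header if c.startswith("clin_")]
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split(sep)
            if len(cells) != len(header):
                raise SchemaError(
                    f"{path}:{lineno}: expected {len(header)} cells, got {len(cells)}"
                )
            raw_tokens = cells[idx["tokens"]]
            tokens = [tok for tok in raw_tokens.split(TOKEN_SEP) if tok != ""]
            meds = {}
            for col in med_cols:
                cell = cells[idx[col]].strip()
                if cell not in ("", "nan"):
                    dose = float(cell)
                    if dose != 0.0:
                        meds[col[len("med_"):]] = dose
            clinical = {}
            for col in clin_cols:
                cell = cells[idx[col]].strip()
                if cell not in ("", "nan"):
                    clinical[col[len("clin_"):]] = float(cell)
            try:
                transcripts.append(
                    Transcript(
                        participant_id=cells[idx["participant_id"]],
                        group=Group.parse(cells[idx["group"]]),
                        tokens=tokens,
                        age=int(cells[idx["age"]]),
                        education=int(cells[idx["education"]]),
                        meds=meds,
                        clinical=clinical,
                    )
                )
            except (ValueError, SchemaError) as exc:
                if isinstance(exc, SchemaError):
                    raise
                raise SchemaError(f"{path}:{lineno}: {exc}") from None
    return Cohort(transcripts, {"source": str(path)})


def write_cohort(cohort: Cohort, path: str | Path, format: str | None = None,
                 sep: str = ";") -> None:
    """Write a cohort as CSV or JSON; round-trips losslessly with read_cohort."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "json":
        payload = {
            "provenance": cohort.provenance,
            "transcripts": [_transcript_to_record(t) for t in cohort],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
        return
    if format != "csv":
        raise ValueError(f"unknown cohort format {format!r}")

    med_cols = sorted({f"med_{d}" for t in cohort for d in t.meds})
    clin_cols = sorted({f"clin_{s}" for t in cohort for s in t.clinical})
    header = _BASE_COLUMNS + med_cols + clin_cols
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(sep.join(header) + "\n")
        for t in cohort:
            for tok in t.tokens:
                if TOKEN_SEP in tok or sep in tok:
                    raise SchemaError(
                        f"token {tok!r} contains a reserved separator"
                    )
            row = [
                t.participant_id,
                t.group.value,
                TOKEN_SEP.join(t.tokens),
                str(t.age),
                str(t.education),
            ]
            row += [repr(t.meds[c[4:]]) if c[4:] in t.meds else "" for c in med_cols]
            row += [repr(t.clinical[c[5:]]) if c[5:] in t.clinical else ""
                    for c in clin_cols]
            fh.write(sep.join(row) + "\n")


# ---------------------------------------------------------------------------
# Score records (written by the scoring module, read back by the stats stage)

_SCORE_COLUMNS = ["participant_id", "group", "fluency", "repetitions",
                  "incorrect", "uniqueness"]


def write_scores(records: Iterable, path: str | Path) -> None:
    """Write ScoreRecords as plain CSV; uniqueness empty when undefined."""
    records = list(records)
    if not records:
        raise ValueError("no score records to write")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(",".join(_SCORE_COLUMNS) + "\n")
        for r in records:
            uniq = "" if r.uniqueness is None else repr(r.uniqueness)
            fh.write(
                f"{r.participant_id},{r.group.value},{r.fluency},"
                f"{r.repetitions},{r.incorrect},{uniq}\n"
            )


def read_scores(path: str | Path) -> list:
    """Read a ScoreRecord CSV written by :func:`write_scores`."""
    from .scoring import ScoreRecord  # local import to avoid a cycle

    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        if header != _SCORE_COLUMNS:
            raise SchemaError(f"{path}: unexpected score columns {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pid, group, flu, rep, inc, uniq = line.split(",")
            out.append(
                ScoreRecord(
                    participant_id=pid,
                    group=Group.parse(group),
                    fluency=int(flu),
                    repetitions=int(rep),
                    incorrect=int(inc),
                    uniqueness=None if uniq == "" else float(uniq),
                )
            )
    return out
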