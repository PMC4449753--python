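"""Species plumage-pattern scoring: states, per-sex motif codes, classification,
and clade-level frequency tabulation.

A species is scored into one of four pattern states — uniform coloration,
irregular patterning (heterogeneous pigmentation without a repeated motif,
e.g. mottling), regular patterning (a repeating motif: bars, scales, spots),
or bimodal patterning (both irregular and regular components, within one sex
or across the two sexes).  Classification is driven by per-sex motif codes;
a species in which only one sex is patterned counts as patterned.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "PatternState",
    "Motif",
    "SpeciesRecord",
    "CharacterMatrix",
    "classify_species",
    "tabulate_frequencies",
    "bimodal_sex_breakdown",
    "read_character_csv",
    "write_character_csv",
    "read_clade_map",
    "read_nexus_states",
    "write_nexus_states",
]


class PatternState(Enum):
    """The four species-level pattern states, in canonical output order."""

    UNIFORM = 0
    IRREGULAR = 1
    REGULAR = 2
    BIMODAL = 3

    def __lt__(self, other: "PatternState") -> bool:
        return self.value < other.value


class Motif(Enum):
    """Per-sex plumage motif codes.

    NONE means uniform coloration for that sex and cannot co-occur with any
    other motif.  MOTTLE (and the OTHER_IRREGULAR escape code) contribute an
    irregular component; BAR, SCALE, SPOT (and OTHER_REGULAR) a regular one.
    """

    NONE = "none"
    MOTTLE = "mottle"
    BAR = "bar"
    SCALE = "scale"
    SPOT = "spot"
    OTHER_IRREGULAR = "other_irregular"
    OTHER_REGULAR = "other_regular"


_IRREGULAR_MOTIFS = {Motif.MOTTLE, Motif.OTHER_IRREGULAR}
_REGULAR_MOTIFS = {Motif.BAR, Motif.SCALE, Motif.SPOT, Motif.OTHER_REGULAR}


class CodingError(ValueError):
    """Raised when a per-sex motif set is invalid."""


def _validate_motifs(motifs: frozenset, taxon: str = "?", sex: str = "?") -> frozenset:
    motifs = frozenset(motifs)
    for m in motifs:
        if not isinstance(m, Motif):
            raise CodingError(f"invalid motif {m!r} for taxon {taxon!r}, sex {sex}")
    if Motif.NONE in motifs and len(motifs) > 1:
        raise CodingError(
            f"NONE cannot co-occur with other motifs (taxon {taxon!r}, sex {sex})"
        )
    if not motifs:
        raise CodingError(f"empty motif set for taxon {taxon!r}, sex {sex}")
    return motifs


def _sex_state(motifs: frozenset) -> PatternState:
    """Pattern state of a single sex from its motif set."""
    irregular = bool(motifs & _IRREGULAR_MOTIFS)
    regular = bool(motifs & _REGULAR_MOTIFS)
    if irregular and regular:
        return PatternState.BIMODAL
    if regular:
        return PatternState.REGULAR
    if irregular:
        return PatternState.IRREGULAR
    return PatternState.UNIFORM


def classify_species(
    male: Iterable[Motif],
    female: Iterable[Motif],
    taxon: str = "?",
) -> PatternState:
    """Classify a species from the motif codes of its two sexes.

    The union of both sexes' pattern components determines the state: both an
    irregular and a regular component present (within one sex or across sexes)
    gives BIMODAL; only regular gives REGULAR; only irregular IRREGULAR; and
    neither gives UNIFORM.  The function is symmetric in its two arguments.
    """
    male = _validate_motifs(frozenset(male), taxon, "male")
    female = _validate_motifs(frozenset(female), taxon, "female")
    union = male | female
    irregular = bool(union & _IRREGULAR_MOTIFS)
    regular = bool(union & _REGULAR_MOTIFS)
    if irregular and regular:
        return PatternState.BIMODAL
    if regular:
        return PatternState.REGULAR
    if irregular:
        return PatternState.IRREGULAR
    return PatternState.UNIFORM


@dataclass(frozen=True)
class SpeciesRecord:
    """One species scoring: taxon label, per-sex motif codes, derived state.

    ``male``/``female`` may be None for state-only records (e.g. read from a
    NEXUS data block).  ``metadata`` carries scoring conventions such as
    breeding-plumage or nominate-subspecies notes; it is not interpreted.
    """

    taxon: str
    male: frozenset | None = None
    female: frozenset | None = None
    state: PatternState | None = None
    metadata: tuple = ()

    def __post_init__(self):
        if self.male is not None and self.female is not None:
            object.__setattr__(self, "male", _validate_motifs(self.male, self.taxon, "male"))
            object.__setattr__(self, "female", _validate_motifs(self.female, self.taxon, "female"))
            derived = classify_species(self.male, self.female, self.taxon)
            if self.state is None:
                object.__setattr__(self, "state", derived)
            elif self.state != derived:
                raise CodingError(
                    f"declared state {self.state.name} for {self.taxon!r} contradicts "
                    f"motif codes (derived {derived.name})"
                )
        elif self.state is None:
            raise CodingError(f"record for {self.taxon!r} has neither motifs nor a state")

    @property
    def has_sex_codes(self) -> bool:
        return self.male is not None and self.female is not None


@dataclass
class CharacterMatrix:
    """A set of species records plus an optional clade map.

    ``clade_map`` maps taxon -> (order, subfamily, tribe-or-subclade); taxa
    absent from it are flagged unassigned at sub-order levels.
    ``clade_order`` optionally fixes row order for tabulated output (e.g. the
    phylogeny's clade sequence); otherwise rows are alphabetical.
    """

    records: list[SpeciesRecord]
    clade_map: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    clade_order: list[str] = field(default_factory=list)

    def __post_init__(self):
        labels = [r.taxon for r in self.records]
        dup = [t for t, c in Counter(labels).items() if c > 1]
        if dup:
            raise ValueError(f"duplicate taxon labels: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def taxa(self) -> list[str]:
        return [r.taxon for r in self.records]

    def states(self) -> dict[str, PatternState]:
        return {r.taxon: r.state for r in self.records}

    def subset(self, taxa: Iterable[str]) -> "CharacterMatrix":
        keep = set(taxa)
        return CharacterMatrix(
            [r for r in self.records if r.taxon in keep],
            dict(self.clade_map),
            list(self.clade_order),
        )


_LEVEL_INDEX = {"order": 0, "subfamily": 1, "tribe": 2}


def tabulate_frequencies(matrix: CharacterMatrix, level: str = "order") -> pd.DataFrame:
    """Percentage of species in each pattern state, per clade at ``level``.

    Returns a DataFrame indexed by clade with columns ``n_species`` and one
    percentage column per state (full precision; round for display).  Taxa
    missing from the clade map are excluded from sub-order rows with a
    warning but are kept in the order-level tabulation (under the dataset's
    order when it is unique, otherwise under ``(unassigned)``).
    """
    if level not in _LEVEL_INDEX:
        raise ValueError(f"level must be one of {sorted(_LEVEL_INDEX)}, got {level!r}")
    if not matrix.records:
        raise ValueError("empty character matrix")
    idx = _LEVEL_INDEX[level]

    assigned_orders = {v[0] for v in matrix.clade_map.values() if v[0]}
    unassigned = [r.taxon for r in matrix.records if r.taxon not in matrix.clade_map]
    if unassigned and matrix.clade_map:
        warnings.warn(
            f"{len(unassigned)} taxa missing from clade map"
            + ("" if level == "order" else f"; excluded from {level}-level rows"),
            stacklevel=2,
        )

    fallback_order = (
        next(iter(assigned_orders)) if len(assigned_orders) == 1 else "(unassigned)"
    )
    groups: dict[str, list[PatternState]] = {}
    for r in matrix.records:
        entry = matrix.clade_map.get(r.taxon)
        if entry is None:
            if level == "order":
                clade = fallback_order
            else:
                continue
        else:
            clade = entry[idx]
            if not clade:
                continue
        groups.setdefault(clade, []).append(r.state)

    if not groups:
        raise ValueError(f"no taxa assigned to any clade at level {level!r}")

    rows = {}
    for clade, states in groups.items():
        n = len(states)
        counts = Counter(states)
        rows[clade] = {
            "n_species": n,
            **{s.name.lower() + "_pct": 100.0 * counts.get(s, 0) / n for s in PatternState},
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    if matrix.clade_order:
        order = [c for c in matrix.clade_order if c in table.index]
        order += [c for c in sorted(table.index) if c not in order]
    else:
        order = sorted(table.index)
    table = table.loc[order]
    table.index.name = level
    return table


def render_frequency_table(table: pd.DataFrame) -> str:
    """Text rendering with 0-decimal percentages and '-' for empty cells."""
    out = table.copy()
    for col in out.columns:
        if col.endswith("_pct"):
            out[col] = [("-" if v == 0 else f"{v:.0f}") for v in out[col]]
    return out.to_string()


def bimodal_sex_breakdown(matrix: CharacterMatrix) -> tuple[float, float, float]:
    """Decompose the bimodal species into three sex-phenotype categories.

    Returns proportions of bimodal species in which (a) both sexes are
    individually bimodal (same phenotype), (b) exactly one sex is bimodal and
    the other carries a singular pattern (or is uniform), and (c) neither sex
    is bimodal — one sex regular, the other irregular.  The three proportions
    sum to 1.  Requires per-sex motif codes on every bimodal record.
    """
    bimodal = [r for r in matrix.records if r.state is PatternState.BIMODAL]
    if not bimodal:
        raise ValueError("no bimodal species in the matrix")
    counts = [0, 0, 0]
    for r in bimodal:
        if not r.has_sex_codes:
            raise ValueError(f"bimodal record {r.taxon!r} lacks per-sex motif codes")
        m, f = _sex_state(r.male), _sex_state(r.female)
        n_bimodal = (m is PatternState.BIMODAL) + (f is PatternState.BIMODAL)
        if n_bimodal == 2:
            counts[0] += 1
        elif n_bimodal == 1:
            counts[1] += 1
        else:
            # species-level bimodality from complementary singular patterns
            counts[2] += 1
    n = len(bimodal)
    return tuple(c / n for c in counts)


# ---------------------------------------------------------------------------
# I/O


def _parse_motifs(cell: str, taxon: str, sex: str) -> frozenset:
    names = [m.strip() for m in cell.split(";") if m.strip()]
    try:
        return frozenset(Motif(n.lower()) for n in names)
    except ValueError as exc:
        raise CodingError(f"invalid motif in {taxon!r} ({sex}): {exc}") from exc


def read_character_csv(path: str | Path) -> CharacterMatrix:
    """Read a character CSV with columns taxon, male_motifs, female_motifs
    (semicolon-separated motif names) and an optional state column that is
    validated against the classification."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "taxon" not in reader.fieldnames:
            raise ValueError(f"{path}: expected a header with a 'taxon' column")
        for row in reader:
            taxon = row["taxon"].strip()
            male = _parse_motifs(row.get("male_motifs", ""), taxon, "male") or None
            female = _parse_motifs(row.get("female_motifs", ""), taxon, "female") or None
            state = None
            if row.get("state", "").strip():
                state = PatternState[row["state"].strip().upper()]
            records.append(SpeciesRecord(taxon, male, female, state))
    return CharacterMatrix(records)


def write_character_csv(matrix: CharacterMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["taxon", "male_motifs", "female_motifs", "state"])
        for r in matrix.records:
            writer.writerow(
                [
                    r.taxon,
                    ";".join(sorted(m.value for m in r.male)) if r.male else "",
                    ";".join(sorted(m.value for m in r.female)) if r.female else "",
                    r.state.name,
                ]
            )


def read_clade_map(path: str | Path) -> tuple[dict, list]:
    """Read a clade-map CSV (taxon, order, subfamily, tribe).

    Returns (mapping, clade_order) where clade_order preserves file order of
    first appearance across all three levels.
    """
    mapping: dict[str, tuple[str, str, str]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            taxon = row["taxon"].strip()
            entry = tuple(row.get(k, "").strip() for k in ("order", "subfamily", "tribe"))
            mapping[taxon] = entry
            for clade in entry:
                if clade and clade not in order:
                    order.append(clade)
    return mapping, order


_NEXUS_SYMBOLS = "0123"


def write_nexus_states(matrix: CharacterMatrix, path: str | Path) -> None:
    """Write species states as a NEXUS data block with the 4-symbol alphabet
    0=uniform, 1=irregular, 2=regular, 3=bimodal."""
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={len(matrix.records)} NCHAR=1;",
        f'    FORMAT DATATYPE=STANDARD SYMBOLS="{_NEXUS_SYMBOLS}";',
        "    MATRIX",
    ]
    for r in matrix.records:
        label = r.taxon.replace(" ", "_")
        lines.append(f"        {label}  {_NEXUS_SYMBOLS[r.state.value]}")
    lines += ["    ;", "END;", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_nexus_states(path: str | Path) -> CharacterMatrix:
    """Read a NEXUS data block written with the 4-symbol alphabet above.

    Records are state-only (no per-sex motif codes)."""
    import dendropy

    cm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    records = []
    for taxon in cm:
        seq = cm[taxon]
        sym = str(seq.symbols_as_string())
        if len(sym) != 1 or sym not in _NEXUS_SYMBOLS:
            raise ValueError(f"{path}: expected one symbol in 0-3 for {taxon.label!r}, got {sym!r}")
        records.append(SpeciesRecord(taxon.label, state=PatternState(int(sym))))
    return CharacterMatrix(records)
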