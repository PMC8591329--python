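"""Two-generation, tactic-structured pedigree: data model, validated I/O, subsetting.

The unit of analysis is an individual salmon with a reproductive tactic
(``female``, ``hooknose`` or ``jack``), a return year, fork length at
maturity (mm) and lifetime reproductive success (number of offspring that
themselves survived to maturity).  A :class:`Pedigree` holds two
generations of such individuals with dam/sire links from the offspring
generation into the parent generation.

Internally the container wraps a :class:`pandas.DataFrame` with one row per
individual and a fixed set of standard columns; all analysis modules accept
either the wrapper or a bare frame with the same columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, PedigreeValidationError

logger = logging.getLogger(__name__)

SEXES = ("female", "male")
TACTICS = ("female", "hooknose", "jack")
MALE_TACTICS = ("hooknose", "jack")
GENERATIONS = ("parent", "offspring")

#: Canonical column order of the internal frame.
STANDARD_COLUMNS = [
    "id", "sex", "tactic", "year", "length_mm", "rs",
    "dam_id", "sire_id", "generation",
]

#: Tokens treated as a missing parent link (case-insensitive) on input.
MISSING_TOKENS = {"", "na", "nan", "none", "null", "missing", "-", "0"}

#: Default jack/hooknose length threshold in mm ("below 500 mm" is strict).
JACK_THRESHOLD_MM = 500.0


@dataclass(frozen=True)
class TacticClassifierRule:
    """Length threshold separating jack from hooknose males.

    Males strictly below ``threshold_mm`` classify as jacks; males at or
    above it as hooknose.  The default of 500 mm reflects the bimodal male
    length distribution in the study population.
    """

    threshold_mm: float = JACK_THRESHOLD_MM

    def __post_init__(self):
        if not self.threshold_mm > 0:
            raise ConfigError(f"threshold_mm must be positive, got {self.threshold_mm}")


def classify_male_tactic(length_mm: float, rule: TacticClassifierRule | None = None) -> str:
    """Classify a male by fork length: ``jack`` iff strictly below the threshold.

    Raises :class:`~tactqg.errors.ConfigError` for nonpositive lengths.
    """
    rule = rule or TacticClassifierRule()
    if not length_mm > 0:
        raise ConfigError(f"length_mm must be positive, got {length_mm}")
    return "jack" if length_mm < rule.threshold_mm else "hooknose"


def _normalize_id(series: pd.Series) -> pd.Series:
    s = series.astype("string").str.strip()
    lowered = s.str.lower()
    return s.mask(s.isna() | lowered.isin(MISSING_TOKENS))


def _validate_frame(df: pd.DataFrame) -> list[str]:
    """Row-level invariant checks; returns a list of diagnostics (empty if valid)."""
    problems: list[str] = []

    dup = df["id"][df["id"].duplicated()].dropna().unique()
    for d in dup:
        problems.append(f"duplicate id {d!r}")
    for idx, row in df[df["id"].isna()].iterrows():
        problems.append(f"row {idx}: missing id")

    bad_sex = ~df["sex"].isin(SEXES)
    for _, row in df[bad_sex].iterrows():
        problems.append(f"id {row['id']!r}: sex {row['sex']!r} not in {SEXES}")
    bad_tactic = ~df["tactic"].isin(TACTICS)
    for _, row in df[bad_tactic].iterrows():
        problems.append(f"id {row['id']!r}: tactic {row['tactic']!r} not in {TACTICS}")

    # tactic == female iff sex == female
    mism = (df["sex"].eq("female") != df["tactic"].eq("female")) & ~bad_sex & ~bad_tactic
    for _, row in df[mism].iterrows():
        problems.append(f"id {row['id']!r}: sex {row['sex']!r} inconsistent with tactic {row['tactic']!r}")

    nonpos = ~(df["length_mm"] > 0)
    for _, row in df[nonpos].iterrows():
        problems.append(f"id {row['id']!r}: length_mm {row['length_mm']!r} not positive")

    rs = pd.to_numeric(df["rs"], errors="coerce")
    bad_rs = rs.isna() | (rs < 0) | (rs != np.floor(rs))
    for _, row in df[bad_rs].iterrows():
        problems.append(f"id {row['id']!r}: rs {row['rs']!r} is not a nonnegative integer")

    bad_gen = ~df["generation"].isin(GENERATIONS)
    for _, row in df[bad_gen].iterrows():
        problems.append(f"id {row['id']!r}: generation {row['generation']!r} not in {GENERATIONS}")

    # referential integrity of parent links (skipped when ids collide;
    # those rows are already reported above)
    sex_by_id = df.set_index(df["id"].astype(object))["sex"]
    for col, want in (("dam_id", "female"), ("sire_id", "male")) if not len(dup) else ():
        links = df[col].dropna()
        missing = links[~links.isin(sex_by_id.index)]
        for ind, pid in zip(df.loc[missing.index, "id"], missing):
            problems.append(f"id {ind!r}: dangling {col} {pid!r}")
        present = links[links.isin(sex_by_id.index)]
        wrong = present[sex_by_id.loc[present].values != want]
        for ind, pid in zip(df.loc[wrong.index, "id"], wrong):
            problems.append(f"id {ind!r}: {col} {pid!r} refers to a non-{want} individual")

    # no individual is its own ancestor (2-generation data, but check generally)
    parents: dict[str, tuple] = {}
    for _, row in df.iterrows():
        parents[row["id"]] = tuple(p for p in (row["dam_id"], row["sire_id"]) if pd.notna(p))
    for start in parents:
        stack, seen = list(parents.get(start, ())), set()
        while stack:
            cur = stack.pop()
            if cur == start:
                problems.append(f"id {start!r}: appears as its own ancestor")
                break
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(parents.get(cur, ()))

    # parent generation strictly precedes the offspring generation in time
    pyears = df.loc[df["generation"].eq("parent"), "year"]
    oyears = df.loc[df["generation"].eq("offspring"), "year"]
    if len(pyears) and len(oyears) and pyears.max() >= oyears.min():
        problems.append(
            f"parent years (max {pyears.max()}) do not precede offspring years (min {oyears.min()})"
        )
    return problems


class Pedigree:
    """Validated container of two generations of tactic-structured individuals.

    Parameters
    ----------
    frame
        One row per individual with the :data:`STANDARD_COLUMNS`.
    validate
        Run the full invariant check (referential integrity, tactic/sex
        consistency, year ordering).  Subsets produced internally skip
        re-validation because dropping rows can only orphan parent links,
        never create new invariant violations at the row level.
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        missing = [c for c in STANDARD_COLUMNS if c not in frame.columns]
        if missing:
            raise ConfigError(f"pedigree frame missing columns: {missing}")
        df = frame.loc[:, STANDARD_COLUMNS].copy()
        df["id"] = _normalize_id(df["id"])
        df["dam_id"] = _normalize_id(df["dam_id"])
        df["sire_id"] = _normalize_id(df["sire_id"])
        for col in ("sex", "tactic", "generation"):
            df[col] = df[col].astype("string")
        df["length_mm"] = pd.to_numeric(df["length_mm"], errors="coerce").astype(float)
        df["year"] = pd.to_numeric(df["year"], errors="coerce").astype("Int64")
        df = df.reset_index(drop=True)
        if validate:
            problems = _validate_frame(df)
            if problems:
                raise PedigreeValidationError(problems)
        df["rs"] = pd.to_numeric(df["rs"], errors="coerce").astype("Int64")
        self._df = df

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:
        n_par = int(self._df["generation"].eq("parent").sum())
        return f"Pedigree(n={len(self)}, parents={n_par}, offspring={len(self) - n_par})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        a = self._df.sort_values("id").reset_index(drop=True)
        b = other._df.sort_values("id").reset_index(drop=True)
        return a.equals(b)

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying individual table (copy-on-write view; do not mutate)."""
        return self._df

    @property
    def parents(self) -> "Pedigree":
        return self.subset(generation="parent")

    @property
    def offspring(self) -> "Pedigree":
        return self.subset(generation="offspring")

    # -- subsetting --------------------------------------------------------
    def subset(
        self,
        years: Optional[Iterable[int]] = None,
        tactics: Optional[Iterable[str]] = None,
        generation: Optional[str] = None,
    ) -> "Pedigree":
        """Filter individuals by year, tactic and/or generation.

        Filter semantics: ``None`` means "no constraint"; an *empty*
        collection is a vacuous filter matching nothing, so
        ``subset(years=set())`` is the empty pedigree.  Composing two
        subsets equals a single subset with intersected filters.
        """
        mask = pd.Series(True, index=self._df.index)
        if years is not None:
            mask &= self._df["year"].isin(list(years))
        if tactics is not None:
            mask &= self._df["tactic"].isin(list(tactics))
        if generation is not None:
            if generation not in GENERATIONS:
                raise ConfigError(f"generation must be one of {GENERATIONS}, got {generation!r}")
            mask &= self._df["generation"].eq(generation)
        return Pedigree(self._df[mask], validate=False)

    # -- family structure --------------------------------------------------
    def family_table(self) -> pd.DataFrame:
        """One record per mated pair with >= 1 offspring in the pedigree.

        Offspring with a single known parent are grouped under that parent
        with a missing co-parent and ``complete=False``.
        """
        off = self._df[self._df["generation"].eq("offspring")]
        off = off[off["dam_id"].notna() | off["sire_id"].notna()]
        if off.empty:
            return pd.DataFrame(columns=["dam_id", "sire_id", "offspring_ids", "n_offspring", "complete"])
        grouped = off.groupby(["dam_id", "sire_id"], dropna=False)["id"].agg(tuple)
        out = grouped.reset_index().rename(columns={"id": "offspring_ids"})
        out["n_offspring"] = out["offspring_ids"].map(len)
        out["complete"] = out["dam_id"].notna() & out["sire_id"].notna()
        return out.sort_values(["dam_id", "sire_id"]).reset_index(drop=True)

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path, sep: str = ",") -> None:
        write_pedigree(self, path, sep=sep)


DEFAULT_DIALECT = {c: c for c in STANDARD_COLUMNS}


def read_pedigree(
    path,
    dialect: Optional[Mapping[str, str]] = None,
    delimiter: Optional[str] = None,
    rule: TacticClassifierRule | None = None,
) -> Pedigree:
    """Read and validate a delimited pedigree table.

    Parameters
    ----------
    path
        CSV/TSV file with one row per individual.
    dialect
        Mapping from standard column names to the file's column names, for
        datasets with different headers.  Unmapped names fall back to
        themselves.  ``tactic``, ``dam_id``, ``sire_id`` and ``generation``
        are optional in the file: tactic is derived from sex and the length
        threshold when absent (present values are kept as-is), and
        generation is inferred as "offspring" iff any parent link is known.
    delimiter
        Field separator; auto-detected when ``None``.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    try:
        if delimiter is None:
            raw = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
        else:
            raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise ConfigError(f"pedigree file not found: {path}") from None

    required = ["id", "sex", "year", "length_mm", "rs"]
    for name in required:
        if mapping[name] not in raw.columns:
            raise ConfigError(f"required column {mapping[name]!r} (for {name!r}) not in {path}")

    df = pd.DataFrame()
    for std in STANDARD_COLUMNS:
        col = mapping[std]
        df[std] = raw[col] if col in raw.columns else pd.NA
    df["id"] = _normalize_id(df["id"])
    df["dam_id"] = _normalize_id(df["dam_id"])
    df["sire_id"] = _normalize_id(df["sire_id"])
    df["sex"] = df["sex"].astype("string").str.strip().str.lower()
    df["year"] = pd.to_numeric(df["year"], errors="coerce").astype("Int64")
    # exact float parsing (pd.to_numeric's fast parser is not round-trip safe)
    lstr = df["length_mm"].astype("string").str.strip()
    df["length_mm"] = lstr.mask(lstr.isna() | lstr.eq("")).map(float, na_action="ignore").astype(float)
    df["rs"] = pd.to_numeric(df["rs"], errors="coerce")

    if mapping["tactic"] in raw.columns:
        df["tactic"] = df["tactic"].astype("string").str.strip().str.lower()
    else:
        # derive: females are their own tactic; males split on the threshold
        df["tactic"] = [
            ("female" if sex == "female" else classify_male_tactic(float(l), rule))
            if pd.notna(l) else pd.NA
            for sex, l in zip(df["sex"], df["length_mm"])
        ]

    if mapping["generation"] in raw.columns:
        df["generation"] = df["generation"].astype("string").str.strip().str.lower()
    else:
        has_parent = df["dam_id"].notna() | df["sire_id"].notna()
        df["generation"] = np.where(has_parent, "offspring", "parent")

    ped = Pedigree(df, validate=True)
    logger.info("read %d individuals from %s", len(ped), path)
    return ped


def write_pedigree(p: Pedigree, path, sep: str = ",") -> None:
    """Write the standard columns; missing parent links become empty fields.

    Lengths are written with "%.17g" so that write → read round-trips
    float64 values exactly.
    """
    df = p.frame.copy()
    df.to_csv(path, sep=sep, index=False, na_rep="", float_format="%.17g")


def apply_study_filters(
    p: Pedigree,
    origin: Optional[Mapping[str, str]] = None,
    wild_value: str = "wild",
) -> tuple[Pedigree, list[dict]]:
    """Explicit, logged inclusion-criteria pass.

    Keeps individuals that (1) have both length and reproductive success
    recorded and, when an origin table is supplied, (2) are of wild origin
    themselves and (3) have both recorded parents of wild origin.  Returns
    the filtered pedigree and a step-by-step accounting of row counts.

    Parameters
    ----------
    origin
        Optional mapping id -> origin label (e.g. ``"wild"`` /
        ``"hatchery"``).  Individuals absent from the mapping fail the
        wild-origin criteria.
    """
    df = p.frame
    log: list[dict] = []

    def _step(name: str, mask: pd.Series, cur: pd.DataFrame) -> pd.DataFrame:
        nxt = cur[mask.loc[cur.index]]
        log.append({"step": name, "before": len(cur), "after": len(nxt)})
        logger.info("filter %s: %d -> %d", name, len(cur), len(nxt))
        return nxt

    cur = _step("length_and_rs_present", df["length_mm"].notna() & df["rs"].notna(), df)
    if origin is not None:
        is_wild = cur["id"].map(lambda i: origin.get(i) == wild_value)
        cur = _step("wild_origin", is_wild, cur)
        parent_wild = pd.Series(True, index=cur.index)
        off = cur["generation"].eq("offspring")
        for col in ("dam_id", "sire_id"):
            ok = cur[col].map(lambda i: pd.notna(i) and origin.get(i) == wild_value)
            parent_wild &= np.where(off, ok, True)
        cur = _step("both_parents_wild", parent_wild, cur)
    return Pedigree(cur, validate=False), log
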