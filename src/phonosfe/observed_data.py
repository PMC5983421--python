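"""Observed language-inventory tables and synthetic fixtures.

Real data are consumed as pre-converted delimited text, one row per
language, giving a distance from the dispersal origin (km, precomputed
great-circle distances) and the language's phoneme inventory.  Two dialects
are supported:

* long — tab-separated with header ``language<TAB>distance_km<TAB>phonemes``,
  the last field a space-separated list of phoneme tokens;
* wide — CSV with header ``language,distance_km,<tok1>,...,<tokP>`` and 0/1
  presence cells.

A fixture generator emulates such tables with a controlled linear
phoneme-count cline plus noise, so the whole observed-data pipeline is
testable without any download.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cline_stats import ClineFit, binned_tf, fit_cline

__all__ = [
    "LanguageRecord",
    "FixtureSpec",
    "read_language_table",
    "write_language_table",
    "records_to_matrix",
    "observed_clines",
    "make_fixture",
]


@dataclass(frozen=True)
class LanguageRecord:
    """One observed language: name, distance from origin, phoneme set."""

    name: str
    distance_km: float
    phonemes: frozenset[str]

    def __post_init__(self) -> None:
        if self.distance_km < 0:
            raise ValueError(f"{self.name}: negative distance")

    @property
    def phoneme_count(self) -> int:
        return len(self.phonemes)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic observed-language table.

    Defaults emulate the shape of the real database (359 languages, 908
    distinct phonemes, a shallow negative count cline from ~37 phonemes at
    the origin).  Generated counts are clipped to >= 1.
    """

    n_languages: int = 359
    nph: int = 908
    intercept: float = 37.0          # phonemes at distance 0
    slope: float = -5e-4             # phonemes per km
    noise_sd: float = 5.0            # phonemes
    max_distance_km: float = 25000.0
    #: master-ordering offset per km; the default walks the full 908-token
    #: ordering across the domain, so every inventory token appears in the
    #: table while neighbouring languages still share most phonemes
    drift_per_km: float = 908.0 / 25000.0
    jitter: int = 3                  # random extra offset per language

    def __post_init__(self) -> None:
        if self.intercept <= 0:
            raise ValueError("intercept must be positive")
        if self.n_languages < 1 or self.nph < 1:
            raise ValueError("sizes must be positive")


def _detect_dialect(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "long" if "\t" in header else "wide"


def read_language_table(path, dialect: str = "auto") -> list[LanguageRecord]:
    """Parse a language table; the master inventory is the union of tokens.

    Raises ``ValueError`` listing every bad row (duplicate names, missing or
    unparsable distances, non-binary wide cells).
    """
    path = Path(path)
    if dialect == "auto":
        dialect = _detect_dialect(path)
    if dialect not in ("long", "wide"):
        raise ValueError("dialect must be 'long', 'wide' or 'auto'")

    records: list[LanguageRecord] = []
    errors: list[str] = []
    seen: set[str] = set()

    if dialect == "long":
        with open(path, "r", encoding="utf-8") as fh:
            rows = list(csv.reader(fh, delimiter="\t"))
        if not rows or [c.strip() for c in rows[0][:2]] != ["language", "distance_km"]:
            raise ValueError("long dialect needs header language<TAB>distance_km<TAB>phonemes")
        for ln, row in enumerate(rows[1:], start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                errors.append(f"line {ln}: expected 3 tab-separated fields")
                continue
            name = row[0].strip()
            if name in seen:
                errors.append(f"line {ln}: duplicate language {name!r}")
                continue
            try:
                dist = float(row[1])
            except ValueError:
                errors.append(f"line {ln}: missing/invalid distance {row[1]!r}")
                continue
            toks = frozenset(row[2].split())
            try:
                records.append(LanguageRecord(name, dist, toks))
            except ValueError as e:
                errors.append(f"line {ln}: {e}")
                continue
            seen.add(name)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        if list(df.columns[:2]) != ["language", "distance_km"]:
            raise ValueError("wide dialect needs header language,distance_km,<tokens...>")
        toks = list(df.columns[2:])
        for ln, row in enumerate(df.itertuples(index=False), start=2):
            name = str(row[0])
            if name in seen:
                errors.append(f"line {ln}: duplicate language {name!r}")
                continue
            try:
                dist = float(row[1])
                if np.isnan(dist):
                    raise ValueError
            except (TypeError, ValueError):
                errors.append(f"line {ln}: missing/invalid distance {row[1]!r}")
                continue
            vals = np.asarray(row[2:], dtype=object)
            bad = [t for t, v in zip(toks, vals) if v not in (0, 1)]
            if bad:
                errors.append(f"line {ln}: non-binary cells for {bad[:3]}")
                continue
            present = frozenset(t for t, v in zip(toks, vals) if v == 1)
            try:
                records.append(LanguageRecord(name, dist, present))
            except ValueError as e:
                errors.append(f"line {ln}: {e}")
                continue
            seen.add(name)

    if errors:
        raise ValueError("bad rows in language table:\n" + "\n".join(errors))
    return records


def write_language_table(records: Sequence[LanguageRecord], path,
                         dialect: str = "long",
                         inventory: Sequence[str] | None = None) -> None:
    """Write records in either dialect (wide needs a column inventory; by
    default the sorted union of tokens)."""
    path = Path(path)
    if dialect == "long":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("language\tdistance_km\tphonemes\n")
            for r in records:
                fh.write(f"{r.name}\t{r.distance_km!r}\t{' '.join(sorted(r.phonemes))}\n")
    elif dialect == "wide":
        toks = list(inventory) if inventory is not None else sorted(
            set().union(*(r.phonemes for r in records)))
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["language", "distance_km"] + toks)
            for r in records:
                w.writerow([r.name, repr(r.distance_km)]
                           + [1 if t in r.phonemes else 0 for t in toks])
    else:
        raise ValueError("dialect must be 'long' or 'wide'")


def records_to_matrix(records: Sequence[LanguageRecord]):
    """(distances, presence matrix, inventory) for a set of records."""
    inventory = sorted(set().union(*(r.phonemes for r in records)))
    index = {t: i for i, t in enumerate(inventory)}
    m = np.zeros((len(records), len(inventory)), dtype=np.uint8)
    for i, r in enumerate(records):
        for t in r.phonemes:
            m[i, index[t]] = 1
    d = np.array([r.distance_km for r in records])
    return d, m, inventory


def observed_clines(records: Sequence[LanguageRecord],
                    bin_km: float = 1000.0) -> tuple[ClineFit, ClineFit]:
    """(phoneme-count cline, binned t_F cline) of an observed table.

    The count cline fits each language's inventory size against its
    distance; the t_F cline fits per-bin diversity (each database language
    weighted once) against bin centers.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 language records")
    d, m, _ = records_to_matrix(records)
    count_fit = fit_cline(d, m.sum(axis=1))
    table = binned_tf(d, m, width_km=bin_km)
    tf_fit = fit_cline(table["bin_center_km"], table["t_F"])
    return count_fit, tf_fit


def make_fixture(spec: FixtureSpec, rng: np.random.Generator) -> list[LanguageRecord]:
    """Generate a synthetic observed-language table with a known cline.

    Distances are uniform on [0, max]; counts follow the linear cline plus
    Gaussian noise (clipped to >= 1).  Phoneme identities are consecutive
    runs of a fixed master ordering starting at an offset that drifts with
    distance (plus a small random jitter), so nearby languages share most of
    their phonemes and the binned t_F is non-degenerate.
    """
    tokens = [f"ph{i:04d}" for i in range(spec.nph)]
    d = rng.uniform(0.0, spec.max_distance_km, size=spec.n_languages)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_languages) if spec.noise_sd > 0 \
        else np.zeros(spec.n_languages)
    counts = np.round(spec.intercept + spec.slope * d + noise).astype(int)
    counts = np.clip(counts, 1, spec.nph)
    out = []
    for i in range(spec.n_languages):
        off = int(round(spec.drift_per_km * d[i])) + int(rng.integers(0, spec.jitter + 1))
        pos = (off + np.arange(counts[i])) % spec.nph
        out.append(LanguageRecord(f"lang{i:04d}", float(d[i]),
                                  frozenset(tokens[p] for p in pos)))
    return out
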