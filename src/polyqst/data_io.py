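"""Readers, writers and validated containers for genotype, trait and site tables.

Canonical on-disk dialect is long-format UTF-8 CSV with a header row:

* genotypes: ``individual_id,population_id,<locus>:<repeat>,...`` where each
  locus cell is a slash-separated list of integer allele lengths in base
  pairs (``281/285``); the repeat-unit length in bp is declared in the
  column header after the colon.  Dosage is unobservable in hexaploids, so a
  cell is a *set* of 1-6 distinct lengths; duplicates are collapsed.
* traits: ``individual_id,chamber_id,<trait>,...`` — one row per
  individual x growth chamber.
* sites: ``population_id,temperature_class,precipitation_class[,lon,lat]``.

Missing cells are empty fields; the missing policy is "flag", never "guess".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "TraitTable",
    "SiteTable",
    "read_genotypes",
    "read_traits",
    "read_sites",
    "write_genotypes",
    "write_traits",
    "write_sites",
    "write_results",
    "GenotypeParseError",
    "TraitValidationError",
]

#: the growth-chamber identifiers of the common-garden design
CHAMBERS = ("ALP1", "ALP4", "BOR1", "BOR4")

#: temperature classes in increasing order of summer temperature
TEMPERATURE_CLASSES = ("ALP", "SUB", "BOR")

MAX_PLOIDY = 6


class GenotypeParseError(ValueError):
    """Raised when a genotype cell cannot be parsed or violates ploidy."""


class TraitValidationError(ValueError):
    """Raised when a trait record violates a sign or count constraint."""


@dataclass
class GenotypeTable:
    """Individuals x loci, each cell a sorted tuple of distinct allele lengths.

    ``data`` has columns ``individual_id``, ``population_id`` and one column
    per locus whose cells are tuples of ints (or ``None`` for missing).
    ``repeat_lengths`` maps locus name -> repeat-unit length in bp.
    """

    data: pd.DataFrame
    repeat_lengths: dict[str, int]

    @property
    def loci(self) -> list[str]:
        return list(self.repeat_lengths)

    @property
    def individuals(self) -> pd.Series:
        return self.data["individual_id"]

    @property
    def populations(self) -> pd.Series:
        return self.data["population_id"]

    def population_ids(self) -> list[str]:
        return list(pd.unique(self.data["population_id"]))

    def validate(self) -> None:
        if self.data["individual_id"].duplicated().any():
            dup = self.data["individual_id"][self.data["individual_id"].duplicated()].iloc[0]
            raise GenotypeParseError(f"duplicate individual_id {dup!r}")
        if self.data["population_id"].isna().any():
            raise GenotypeParseError("individual without a population label")
        for locus in self.loci:
            if locus not in self.data.columns:
                raise GenotypeParseError(f"locus {locus!r} missing from table")
            for ind, cell in zip(self.data["individual_id"], self.data[locus]):
                if cell is None:
                    continue
                if not cell or len(cell) > MAX_PLOIDY:
                    raise GenotypeParseError(
                        f"individual {ind!r}, locus {locus!r}: allele set of "
                        f"size {len(cell)} outside 1..{MAX_PLOIDY}"
                    )
                if list(cell) != sorted(set(cell)):
                    raise GenotypeParseError(
                        f"individual {ind!r}, locus {locus!r}: allele set not "
                        "deduplicated/sorted"
                    )

    def subset_individuals(self, keep: list[str]) -> "GenotypeTable":
        mask = self.data["individual_id"].isin(keep)
        return GenotypeTable(self.data.loc[mask].reset_index(drop=True), dict(self.repeat_lengths))


# the 12 traits of the growth-chamber experiment, in report order
TRAIT_NAMES = (
    "plant_height",
    "total_ramets",
    "pct_extravaginal_ramets",
    "aboveground_biomass",
    "belowground_biomass",
    "rhizome_biomass",
    "below_above_ratio",
    "phi_p0",
    "pi_abs",
    "water_potential",
    "stomata_density",
    "stomata_size",
)

_COUNT_TRAITS = {"total_ramets", "intravaginal_ramets", "extravaginal_ramets"}
_NONNEG_TRAITS = _COUNT_TRAITS | {
    "plant_height",
    "aboveground_biomass",
    "belowground_biomass",
    "rhizome_biomass",
    "stomata_density",
    "stomata_size",
}


@dataclass
class TraitTable:
    """One record per individual x growth chamber; wide trait columns."""

    data: pd.DataFrame
    trait_names: tuple[str, ...] = TRAIT_NAMES

    def validate(self) -> None:
        key = self.data[["individual_id", "chamber_id"]]
        if key.duplicated().any():
            row = key[key.duplicated()].iloc[0]
            raise TraitValidationError(
                f"duplicate record for individual {row['individual_id']!r} "
                f"chamber {row['chamber_id']!r}"
            )
        for name in self.trait_names:
            if name not in self.data.columns:
                raise TraitValidationError(f"missing trait column {name!r}")
        if "pct_extravaginal_ramets" in self.data.columns:
            pct = self.data["pct_extravaginal_ramets"].dropna()
            if ((pct < 0) | (pct > 100)).any():
                raise TraitValidationError("% extravaginal ramets outside [0, 100]")
        for name in _NONNEG_TRAITS & set(self.data.columns):
            col = self.data[name].dropna()
            bad = col[col < 0]
            if len(bad):
                raise TraitValidationError(
                    f"negative value for {name!r} at row {bad.index[0]}"
                )
        for name in _COUNT_TRAITS & set(self.data.columns):
            col = self.data[name].dropna()
            if not np.allclose(col, np.round(col)):
                raise TraitValidationError(f"non-integer count in {name!r}")


@dataclass
class SiteTable:
    """Population -> position on the crossed temperature x precipitation grid."""

    data: pd.DataFrame

    def validate(self, genotypes: GenotypeTable | None = None) -> None:
        if self.data["population_id"].duplicated().any():
            raise ValueError("duplicate population_id in site table")
        bad_t = set(self.data["temperature_class"]) - set(TEMPERATURE_CLASSES)
        if bad_t:
            raise ValueError(f"unknown temperature class(es) {sorted(bad_t)}")
        bad_p = set(self.data["precipitation_class"].astype(int)) - {1, 2, 3, 4}
        if bad_p:
            raise ValueError(f"precipitation class(es) outside 1-4: {sorted(bad_p)}")
        if genotypes is not None:
            missing = set(genotypes.population_ids()) - set(self.data["population_id"])
            if missing:
                raise ValueError(f"populations without a site record: {sorted(missing)}")

    def temperature_code(self) -> pd.Series:
        """Ordinal coding ALP=1, SUB=2, BOR=3 (increasing temperature)."""
        codes = {c: i + 1 for i, c in enumerate(TEMPERATURE_CLASSES)}
        return self.data["temperature_class"].map(codes)


def _parse_allele_cell(raw: str, individual: str, locus: str) -> tuple[int, ...] | None:
    raw = raw.strip()
    if not raw:
        return None
    try:
        alleles = sorted({int(tok) for tok in raw.split("/")})
    except ValueError as exc:
        raise GenotypeParseError(
            f"individual {individual!r}, locus {locus!r}: unparseable allele "
            f"field {raw!r}"
        ) from exc
    if len(alleles) > MAX_PLOIDY:
        raise GenotypeParseError(
            f"individual {individual!r}, locus {locus!r}: {len(alleles)} distinct "
            f"alleles exceeds ploidy {MAX_PLOIDY}"
        )
    return tuple(alleles)


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read the canonical genotype CSV (see module docstring for the dialect)."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(raw.columns[:2]) != ["individual_id", "population_id"]:
        raise GenotypeParseError(
            "genotype CSV must start with individual_id,population_id columns"
        )
    repeat_lengths: dict[str, int] = {}
    locus_cols: dict[str, str] = {}
    for col in raw.columns[2:]:
        if ":" not in col:
            raise GenotypeParseError(
                f"locus column {col!r} lacks ':<repeat>' suffix declaring the "
                "repeat-unit length"
            )
        locus, rep = col.rsplit(":", 1)
        repeat_lengths[locus] = int(rep)
        locus_cols[col] = locus
    data = raw[["individual_id", "population_id"]].copy()
    for col, locus in locus_cols.items():
        data[locus] = [
            _parse_allele_cell(v, ind, locus)
            for v, ind in zip(raw[col], raw["individual_id"])
        ]
    table = GenotypeTable(data, repeat_lengths)
    table.validate()
    return table


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    out = table.data[["individual_id", "population_id"]].copy()
    for locus, rep in table.repeat_lengths.items():
        out[f"{locus}:{rep}"] = [
            "" if cell is None else "/".join(str(a) for a in cell)
            for cell in table.data[locus]
        ]
    out.to_csv(path, index=False)


def read_traits(path: str | Path, trait_names: tuple[str, ...] | None = None) -> TraitTable:
    """Read the trait CSV; derive total ramets / %-extravaginal / below:above
    ratio when the raw components are present and the derived column absent.

    ``trait_names=None`` takes every non-key column as a trait.
    """
    data = pd.read_csv(path)
    if "individual_id" not in data.columns or "chamber_id" not in data.columns:
        raise TraitValidationError("trait CSV needs individual_id and chamber_id")
    data = derive_composite_traits(data)
    if trait_names is None:
        trait_names = tuple(
            c for c in data.columns if c not in ("individual_id", "chamber_id")
        )
    table = TraitTable(data, trait_names)
    table.validate()
    return table


def derive_composite_traits(data: pd.DataFrame) -> pd.DataFrame:
    """Fill in total ramets, % extravaginal and below:above ratio if derivable.

    Total ramets is the sum of intra- and extravaginal ramet counts.  The
    ratio is left NA (not an error) where aboveground biomass is zero.
    """
    data = data.copy()
    have = set(data.columns)
    if {"intravaginal_ramets", "extravaginal_ramets"} <= have:
        if "total_ramets" not in have:
            data["total_ramets"] = data["intravaginal_ramets"] + data["extravaginal_ramets"]
        if "pct_extravaginal_ramets" not in have:
            tot = data["total_ramets"].where(data["total_ramets"] > 0)
            data["pct_extravaginal_ramets"] = 100.0 * data["extravaginal_ramets"] / tot
    if {"aboveground_biomass", "belowground_biomass"} <= have and "below_above_ratio" not in have:
        above = data["aboveground_biomass"].where(data["aboveground_biomass"] != 0)
        data["below_above_ratio"] = data["belowground_biomass"] / above
    return data


def write_traits(table: TraitTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def read_sites(path: str | Path) -> SiteTable:
    data = pd.read_csv(path)
    table = SiteTable(data)
    table.validate()
    return table


def write_sites(table: SiteTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    manifest: dict | None = None,
    force: bool = False,
) -> list[Path]:
    """Write result tables as ``<name>.csv`` plus a JSON run manifest.

    Refuses to overwrite existing files unless ``force``.  An empty result
    set still writes the manifest so a run is always auditable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    targets = {name: out_dir / f"{name}.csv" for name in tables}
    targets["manifest"] = out_dir / "manifest.json"
    if not force:
        clashes = [p for p in targets.values() if p.exists()]
        if clashes:
            raise FileExistsError(
                f"refusing to overwrite {clashes[0]} (pass force=True / --force)"
            )
    for name, df in tables.items():
        df.to_csv(targets[name], index=False)
        written.append(targets[name])
    payload = dict(manifest or {})
    payload.setdefault("tables", sorted(tables))
    targets["manifest"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    written.append(targets["manifest"])
    return written
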