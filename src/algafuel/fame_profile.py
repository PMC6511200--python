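"""Fatty-acid methyl-ester (FAME) composition profiles.

A FAME profile records, for one strain grown at one dilution rate, the mass
percentage of each fatty-acid species in the total fatty-acid pool, as
obtained from GC analysis of transesterified biomass.  Profiles are the
input to the empirical biodiesel property models in
:mod:`algafuel.fuel_properties`.

Conventions
-----------
* Fatty acids are named ``C{carbons}:{double bonds}n{omega}`` (the omega
  suffix is informational and optional), e.g. ``C16:1n7`` for palmitoleic
  acid.  The parser also accepts the bare dialect ``16:1n7`` and the hyphen
  form ``C16:1n-7``.
* Species reported as absent (printed "–" in composition tables) count as
  exactly 0 % downstream.
* Profiles may legitimately total below 100 % (the remainder being
  unidentified fatty acids); totals are never renormalized.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FattyAcid",
    "FameProfile",
    "SaturationClass",
    "SaturationSummary",
    "parse_fatty_acid",
    "classify",
    "saturation_summary",
    "read_profiles_long",
    "read_profiles_wide",
    "write_profiles_long",
    "write_profiles_wide",
    "profiles_to_wide_frame",
]

#: Upper slack allowed on a profile's total mass fraction.  Published
#: composition tables overshoot 100 not only through per-entry print
#: rounding but also through mis-printed entries (the packaged reference
#: table has a column totalling 104.6); such profiles must still load so
#: they can be inspected and flagged.
TOTAL_TOLERANCE = 5.0

#: Strings treated as "absent" (i.e. exactly zero) in composition tables.
ABSENT_TOKENS = {"", "-", "–", "—", "na", "nd"}


class SaturationClass(str, enum.Enum):
    """Saturation class of a fatty acid."""

    SFA = "SFA"
    MUFA = "MUFA"
    PUFA = "PUFA"


@dataclass(frozen=True, order=True)
class FattyAcid:
    """A fatty-acid species identified by chain length, unsaturation and
    (optionally) omega class.

    Identity for dict keys is the full triple, so C18:1n9 and C18:1n7 are
    distinct entries.
    """

    carbon_count: int
    double_bonds: int
    omega_class: int | None = None

    def __post_init__(self) -> None:
        if not 4 <= self.carbon_count <= 30:
            raise ValueError(
                f"carbon_count {self.carbon_count} outside the supported "
                f"range [4, 30]"
            )
        if not 0 <= self.double_bonds <= 6:
            raise ValueError(
                f"double_bonds {self.double_bonds} outside the supported "
                f"range [0, 6]"
            )
        if self.double_bonds >= self.carbon_count / 2:
            raise ValueError(
                f"{self.double_bonds} double bonds is chemically impossible "
                f"for a C{self.carbon_count} chain"
            )
        if self.omega_class is not None and self.omega_class < 1:
            raise ValueError(f"omega_class must be >= 1, got {self.omega_class}")

    @property
    def canonical_name(self) -> str:
        name = f"C{self.carbon_count}:{self.double_bonds}"
        if self.omega_class is not None:
            name += f"n{self.omega_class}"
        return name

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_name


_FA_PATTERN = re.compile(r"^[Cc]?(\d+):(\d+)(?:n-?(\d+))?$")


def parse_fatty_acid(name: str) -> FattyAcid:
    """Parse a fatty-acid label such as ``"16:1n7"`` or ``"C18:0"``.

    Accepts an optional leading ``C``, an optional omega suffix ``n7`` or
    ``n-7``, and surrounding whitespace.  Raises :class:`ValueError` naming
    the offending token for anything else.
    """
    token = name.strip()
    m = _FA_PATTERN.match(token)
    if m is None:
        raise ValueError(f"cannot parse fatty-acid name {name!r}")
    carbons, bonds, omega = m.groups()
    return FattyAcid(
        carbon_count=int(carbons),
        double_bonds=int(bonds),
        omega_class=int(omega) if omega is not None else None,
    )


def classify(fa: FattyAcid) -> SaturationClass:
    """Saturation class: SFA (0 double bonds), MUFA (1) or PUFA (>= 2)."""
    if fa.double_bonds == 0:
        return SaturationClass.SFA
    if fa.double_bonds == 1:
        return SaturationClass.MUFA
    return SaturationClass.PUFA


@dataclass
class FameProfile:
    """FAME composition of one strain x dilution-rate condition.

    Parameters
    ----------
    strain:
        Strain label, e.g. ``"Chlorella"``.
    dilution_rate:
        Dilution rate of the culture the biomass was harvested from (1/day).
    fractions:
        Mapping of fatty acid to mass percent of total fatty acids (0-100).
        Absent species may simply be omitted; they count as zero.
    provenance:
        Free-text note on where the numbers came from.
    """

    strain: str
    dilution_rate: float
    fractions: dict[FattyAcid, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.dilution_rate < 0:
            raise ValueError("dilution_rate must be >= 0")
        for fa, pct in self.fractions.items():
            if pct < 0:
                raise ValueError(f"negative fraction {pct} for {fa.canonical_name}")
        total = sum(self.fractions.values())
        if total > 100.0 + TOTAL_TOLERANCE:
            raise ValueError(f"profile fractions total {total:.2f} > 100")

    @property
    def condition(self) -> str:
        """Condition label ``strain@D`` used as a table column name."""
        return f"{self.strain}@{self.dilution_rate:.2f}"

    @property
    def total(self) -> float:
        """Sum of all reported fractions (may be below 100)."""
        return sum(self.fractions.values())

    def fraction(self, fa: FattyAcid) -> float:
        return self.fractions.get(fa, 0.0)


@dataclass(frozen=True)
class SaturationSummary:
    """Class sums and average unsaturation of a profile.

    ``average_unsaturation`` (ACU) is the fraction-weighted mean number of
    double bonds, ``sum(double_bonds * percent) / 100``, the single covariate
    of the empirical fuel-property regressions.
    """

    sfa: float
    mufa: float
    pufa: float
    average_unsaturation: float


def saturation_summary(profile: FameProfile) -> SaturationSummary:
    """Sum a profile into SFA/MUFA/PUFA classes and compute ACU.

    Sub-100 totals are preserved: the three class sums add up to the
    profile's reported total, not to 100.
    """
    if not profile.fractions:
        raise ValueError("cannot summarize an empty profile")
    sums = {cls: 0.0 for cls in SaturationClass}
    acu = 0.0
    for fa, pct in profile.fractions.items():
        sums[classify(fa)] += pct
        acu += fa.double_bonds * pct
    return SaturationSummary(
        sfa=sums[SaturationClass.SFA],
        mufa=sums[SaturationClass.MUFA],
        pufa=sums[SaturationClass.PUFA],
        average_unsaturation=acu / 100.0,
    )


# ---------------------------------------------------------------------------
# CSV I/O
#
# Long format:  strain,dilution_rate,fatty_acid,percent      (one row per FA)
# Wide format:  fatty_acid,<strain>@<D>,...                  (one col per
#               condition; "–" or empty cells mean absent, i.e. 0)
# ---------------------------------------------------------------------------


def _cell_to_fraction(value: object) -> float:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return 0.0
    text = str(value).strip()
    if text.lower() in ABSENT_TOKENS:
        return 0.0
    try:
        return float(text)
    except ValueError as exc:
        raise ValueError(f"non-numeric composition cell {value!r}") from exc


def _parse_condition(label: str) -> tuple[str, float]:
    strain, sep, rate = str(label).partition("@")
    if not sep:
        raise ValueError(
            f"wide-format column {label!r} is not of the form 'strain@dilution'"
        )
    return strain, float(rate)


def read_profiles_long(path) -> list[FameProfile]:
    """Read profiles from a long-format CSV."""
    frame = pd.read_csv(path, dtype=str)
    required = {"strain", "dilution_rate", "fatty_acid", "percent"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"long-format CSV missing columns {sorted(missing)}")
    profiles: dict[tuple[str, float], FameProfile] = {}
    for row in frame.itertuples(index=False):
        key = (row.strain, float(row.dilution_rate))
        prof = profiles.get(key)
        if prof is None:
            prof = FameProfile(strain=row.strain, dilution_rate=key[1],
                               provenance=str(path))
            profiles[key] = prof
        fa = parse_fatty_acid(row.fatty_acid)
        pct = _cell_to_fraction(row.percent)
        if fa in prof.fractions:
            raise ValueError(
                f"duplicate fatty acid {fa.canonical_name} for condition "
                f"{prof.condition}"
            )
        prof.fractions[fa] = pct
    return list(profiles.values())


def read_profiles_wide(path) -> list[FameProfile]:
    """Read profiles from a wide-format CSV (one column per condition)."""
    frame = pd.read_csv(path, dtype=str)
    if frame.columns[0] != "fatty_acid":
        raise ValueError("wide-format CSV must start with a 'fatty_acid' column")
    fas = [parse_fatty_acid(name) for name in frame["fatty_acid"]]
    if len(set(fas)) != len(fas):
        raise ValueError("duplicate fatty-acid rows in wide-format CSV")
    profiles = []
    for col in frame.columns[1:]:
        strain, rate = _parse_condition(col)
        fractions = {
            fa: _cell_to_fraction(cell) for fa, cell in zip(fas, frame[col])
        }
        # keep explicit zeros out of the mapping: absent means absent
        fractions = {fa: pct for fa, pct in fractions.items() if pct > 0.0}
        profiles.append(
            FameProfile(strain=strain, dilution_rate=rate,
                        fractions=fractions, provenance=str(path))
        )
    return profiles


def profiles_to_wide_frame(profiles: Iterable[FameProfile]) -> pd.DataFrame:
    """Tabulate profiles as a wide DataFrame (rows FAs, columns conditions).

    Values are reported to 2 decimal places; absent species become 0.0.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to tabulate")
    all_fas = sorted({fa for p in profiles for fa in p.fractions})
    data = {
        p.condition: [round(p.fraction(fa), 2) for fa in all_fas]
        for p in profiles
    }
    return pd.DataFrame(data, index=[fa.canonical_name for fa in all_fas])


def write_profiles_wide(profiles: Iterable[FameProfile], path) -> None:
    frame = profiles_to_wide_frame(profiles)
    frame.index.name = "fatty_acid"
    frame.to_csv(path)


def write_profiles_long(profiles: Iterable[FameProfile], path) -> None:
    rows = [
        {
            "strain": p.strain,
            "dilution_rate": p.dilution_rate,
            "fatty_acid": fa.canonical_name,
            "percent": round(pct, 2),
        }
        for p in profiles
        for fa, pct in sorted(p.fractions.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
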