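"""Community invasibility metrics on site x species density tables.

Densities are individuals per 100 m² of sampled stream. Invasibility is
measured through the non-native component of the assemblage: frequency of
occurrence of non-native species (NNS), the per-site fraction of species
richness that is non-native, and pooled mean densities. For GLM density
responses the continuous density is standardised to the species maximum and
collapsed to four ordinal classes (0: absent; 1: up to 10% of the maximum;
2: 10-50%; 3: above 50%), which sidesteps the distribution-fitting problems
caused by the very high number of zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ORIGINS = ("native", "non_native", "diadromous")


@dataclass(frozen=True)
class SpeciesInfo:
    """A species name with its biogeographic origin."""

    name: str
    origin: str

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(
                f"origin must be one of {ORIGINS}, got {self.origin!r}")


class SpeciesDensityTable:
    """Site x species density matrix with per-species origin flags.

    Parameters
    ----------
    density : DataFrame
        Sites in rows (index = site ids), species in columns, non-negative
        densities in individuals/100 m².
    species : sequence of SpeciesInfo
        One entry per density column; names must match the columns.
    """

    def __init__(self, density: pd.DataFrame, species: Sequence[SpeciesInfo]):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        if set(names) != set(density.columns):
            raise ValueError("species list does not match density columns")
        if (density.to_numpy() < 0).any():
            raise ValueError("densities must be non-negative")
        self.density = density.loc[:, names].astype(float)
        self.species = list(species)

    # -- basic accessors -------------------------------------------------
    @property
    def sites(self) -> pd.Index:
        return self.density.index

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def origin_of(self, name: str) -> str:
        for s in self.species:
            if s.name == name:
                return s.origin
        raise KeyError(name)

    def nonnative_names(self) -> list[str]:
        return [s.name for s in self.species if s.origin == "non_native"]

    # -- IO ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the wide layout: one row per site, a column per species."""
        frame = self.density.copy()
        frame.insert(0, "site_id", frame.index)
        frame.to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   origins: dict[str, str]) -> "SpeciesDensityTable":
        """Build from a wide frame (``site_id`` column plus species columns)."""
        frame = frame.set_index("site_id") if "site_id" in frame.columns else frame
        species = [SpeciesInfo(name, origins[name]) for name in frame.columns]
        return cls(frame, species)


def _resolve_species(table: SpeciesDensityTable,
                     species_subset: Iterable[str] | None) -> list[str]:
    if species_subset is None:
        subset = table.nonnative_names()
    else:
        subset = list(species_subset)
        unknown = set(subset) - set(table.species_names)
        if unknown:
            raise ValueError(f"unknown species: {sorted(unknown)}")
    if not subset:
        raise ValueError("empty species subset")
    return subset


def frequency_of_occurrence(
    table: SpeciesDensityTable,
    species_subset: Iterable[str] | None = None,
    site_subset: Iterable | None = None,
) -> float:
    """Proportion of sites where at least one selected species is present.

    ``species_subset`` defaults to all non-native species, which yields the
    pooled NNS frequency of occurrence.
    """
    species = _resolve_species(table, species_subset)
    sites = table.sites if site_subset is None else pd.Index(list(site_subset))
    if len(sites) == 0:
        raise ValueError("empty site subset")
    unknown = set(sites) - set(table.sites)
    if unknown:
        raise ValueError(f"unknown sites: {sorted(map(str, unknown))}")
    sub = table.density.loc[sites, species]
    return float((sub.to_numpy() > 0).any(axis=1).mean())


def nns_richness_fraction(table: SpeciesDensityTable, site) -> float:
    """Fraction of the species present at a site that are non-native.

    Returns 0 when no fish at all are present at the site.
    """
    if site not in table.sites:
        raise ValueError(f"unknown site: {site!r}")
    row = table.density.loc[site]
    present = row[row > 0].index
    if len(present) == 0:
        return 0.0
    nns = set(table.nonnative_names())
    return float(sum(name in nns for name in present) / len(present))


def pooled_weighted_mean(group_means: Sequence[tuple[float, int]]) -> float:
    """Pool per-group means into an overall mean, weighting by group size.

    Reconstructs survey-wide mean densities from per-river-type cells:
    sum(mean_i * n_i) / sum(n_i). Groups without occurrences contribute a
    mean of 0 with their full n.
    """
    if len(group_means) == 0:
        raise ValueError("group_means must be non-empty")
    means = np.array([m for m, _ in group_means], dtype=float)
    ns = np.array([n for _, n in group_means], dtype=float)
    if (ns <= 0).any():
        raise ValueError("all group sizes must be > 0")
    return float((means * ns).sum() / ns.sum())


def density_to_class(density: float, species_max: float) -> int:
    """Collapse a density to its four-class ordinal code.

    The density is standardised to the species maximum over the analysed
    data; class 0 is absence, class 1 covers ratios in (0, 0.10], class 2
    (0.10, 0.50] and class 3 everything above 0.50 (boundaries fall to the
    lower class so the four classes partition [0, 1]).
    """
    if species_max <= 0:
        raise ValueError("species_max must be > 0")
    if density < 0 or density > species_max:
        raise ValueError("density must lie in [0, species_max]")
    if density == 0:
        return 0
    ratio = density / species_max
    if ratio <= 0.10:
        return 1
    if ratio <= 0.50:
        return 2
    return 3


def density_class_frame(table: SpeciesDensityTable,
                        species: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-site density classes for the selected species.

    The species maximum is taken over the whole table (all analysed sites).
    Species that never occur are all-zero and are returned as class 0
    throughout.
    """
    names = _resolve_species(table, species)
    out = {}
    for name in names:
        col = table.density[name]
        mx = float(col.max())
        if mx == 0:
            out[name] = np.zeros(len(col), dtype=int)
        else:
            out[name] = np.array([density_to_class(v, mx) for v in col])
    return pd.DataFrame(out, index=table.sites)


def type_summary(
    table: SpeciesDensityTable,
    sites: pd.DataFrame,
    reference: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-river-type invasibility summary (pooled / reference / disturbed).

    For each river type and site stratum, reports the number of sites, the
    pooled NNS frequency of occurrence, the mean per-site non-native
    richness fraction (in %) and the mean and SD of the summed NNS density.
    """
    if "river_type" not in sites.columns:
        raise ValueError("site table must carry a river_type column")
    site_ids = sites["site_id"] if "site_id" in sites.columns else sites.index
    nns = table.nonnative_names()
    rows = []
    strata: dict[str, pd.Series] = {"all": pd.Series(True, index=table.sites)}
    if reference is not None:
        ref = pd.Series(reference).astype(bool)
        ref.index = table.sites
        strata["reference"] = ref
        strata["disturbed"] = ~ref
    by_type = pd.Series(sites["river_type"].to_numpy(), index=pd.Index(site_ids))
    for rt in pd.unique(by_type):
        type_sites = by_type.index[by_type == rt]
        for stratum, mask in strata.items():
            sel = [s for s in type_sites if mask.loc[s]]
            if not sel:
                continue
            dens = table.density.loc[sel, nns].sum(axis=1) if nns else pd.Series(0.0, index=sel)
            foc = (frequency_of_occurrence(table, site_subset=sel)
                   if nns else 0.0)
            frac = np.mean([nns_richness_fraction(table, s) for s in sel])
            rows.append({
                "river_type": rt, "stratum": stratum, "n_sites": len(sel),
                "nns_foc": foc, "nns_richness_pct": 100 * float(frac),
                "nns_density_mean": float(dens.mean()),
                "nns_density_sd": float(dens.std(ddof=1)) if len(sel) > 1 else 0.0,
            })
    return pd.DataFrame(rows)
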