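"""Trend-surface spatial descriptors and GLM deviance partitioning.

The explained deviance of a GLM response (occurrence or density class of a
non-native species) is decomposed over three predictor sets — environmental
(E), human-pressure (P) and spatial (S) — into eight components by
inclusion-exclusion over the seven models E, P, S, E∪P, E∪S, P∪S, E∪P∪S.
With D(X) = 1 - residual/null deviance of model X:

    pure E            a = D(EPS) - D(PS)
    pure P            b = D(EPS) - D(ES)
    pure S            c = D(EPS) - D(EP)
    three-way shared  g = D(E)+D(P)+D(S) - D(EP)-D(ES)-D(PS) + D(EPS)
    shared E∩P        d = D(E)+D(P) - D(EP) - g
    shared E∩S        e = D(E)+D(S) - D(ES) - g
    shared P∩S        f = D(P)+D(S) - D(PS) - g
    unexplained       h = 1 - D(EPS)

These sum to one identically. Shared components can come out negative
(suppression between sets); they are reported as computed, never clamped,
since clamping would silently break the sum-to-one identity.

The spatial set is the cubic trend surface in site coordinates: x and y are
centred to zero mean (reducing collinearity between successive polynomial
terms) and expanded into the nine terms x, y, xy, x², y², x²y, xy², x³, y³.

:class:`DeviancePartition` is the model object (data + response + the three
term sets); its :meth:`~DeviancePartition.fit` forward-selects a minimal
adequate subset within each set (AIC under the VIF cap; switchable to
full-set partitioning) and returns a :class:`DeviancePartitionResults`
carrying the fractions, the seven sub-model fits, the per-set selection
traces and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .glm import GlmFit, GlmSpec, SelectionTrace, fit_glm, forward_select

SPATIAL_TERMS = ("x", "y", "xy", "x2", "y2", "x2y", "xy2", "x3", "y3")


def build_spatial_terms(coordinates: pd.DataFrame,
                        prefix: str = "spatial_") -> pd.DataFrame:
    """Cubic trend-surface descriptors from site coordinates.

    ``coordinates`` needs columns ``x`` and ``y`` (any planar projection;
    only relative positions matter). Both are centred to zero mean before
    the nine polynomial terms are formed. Missing coordinates raise with
    the offending site named.
    """
    for c in ("x", "y"):
        if c not in coordinates.columns:
            raise ValueError(f"coordinates must have an {c!r} column")
        bad = coordinates.index[coordinates[c].isna()]
        if len(bad):
            raise ValueError(f"missing {c!r} coordinate for site(s) "
                             f"{list(map(str, bad[:5]))}")
    x = coordinates["x"].astype(float)
    y = coordinates["y"].astype(float)
    x = x - x.mean()
    y = y - y.mean()
    terms = {
        "x": x, "y": y, "xy": x * y, "x2": x ** 2, "y2": y ** 2,
        "x2y": x ** 2 * y, "xy2": x * y ** 2, "x3": x ** 3, "y3": y ** 3,
    }
    return pd.DataFrame({prefix + k: v for k, v in terms.items()},
                        index=coordinates.index)


def explained_fraction(fit: GlmFit) -> float:
    """Explained deviance D = 1 - residual/null of a converged fit."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    return fit.explained_fraction


@dataclass(frozen=True)
class DevianceFractions:
    """The eight deviance-partition components, as fractions of null deviance."""

    pure_env: float
    pure_pressure: float
    pure_spatial: float
    env_pressure: float
    env_spatial: float
    pressure_spatial: float
    three_way: float
    unexplained: float

    _LETTERS = ("a", "b", "c", "d", "e", "f", "g", "h")

    def to_series(self) -> pd.Series:
        return pd.Series({
            "pure_env": self.pure_env,
            "pure_pressure": self.pure_pressure,
            "pure_spatial": self.pure_spatial,
            "env_pressure": self.env_pressure,
            "env_spatial": self.env_spatial,
            "pressure_spatial": self.pressure_spatial,
            "three_way": self.three_way,
            "unexplained": self.unexplained,
        })

    def total(self) -> float:
        return float(self.to_series().sum())


class DeviancePartition:
    """Deviance-partition model over environmental/pressure/spatial sets.

    Parameters
    ----------
    data : DataFrame
        Site table holding the response and every predictor column.
    response : str
        Response column: 0/1 occurrence (binomial) or 0-3 density class
        (Poisson).
    family : str
        ``"binomial_logit"``, ``"poisson_log"`` or (for the identity-link
        special case used in cross-checks) ``"gaussian_identity"``.
    sets : mapping
        ``{"E": [...], "P": [...], "S": [...]}`` term lists; sets must be
        disjoint and may be empty (an empty set contributes zero to every
        component involving it).
    select : bool
        Forward-select a minimal adequate subset within each set before
        partitioning (default); ``False`` partitions over the full sets.
    vif_cap : float
        VIF admissibility cap during selection.
    """

    def __init__(self, data: pd.DataFrame, response: str, family: str,
                 sets: Mapping[str, Sequence[str]], select: bool = True,
                 vif_cap: float = 3.0):
        self.sets = {k: tuple(sets.get(k, ())) for k in ("E", "P", "S")}
        all_terms = [t for terms in self.sets.values() for t in terms]
        if len(set(all_terms)) != len(all_terms):
            raise ValueError("E, P and S term sets must be disjoint")
        cols = [response, *all_terms]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"columns not in data: {missing}")
        self.data = data.dropna(subset=cols).copy()  # listwise, so all 7
        self.response = response                     # models share rows
        self.family = family
        self.select = select
        self.vif_cap = vif_cap

    @classmethod
    def from_coordinates(cls, data: pd.DataFrame, response: str, family: str,
                         env_terms: Sequence[str],
                         pressure_terms: Sequence[str],
                         coord_cols: tuple[str, str] = ("x", "y"),
                         **kwargs) -> "DeviancePartition":
        """Build the model with the spatial set derived from coordinates."""
        coords = data[list(coord_cols)].rename(
            columns=dict(zip(coord_cols, ("x", "y"))))
        spatial = build_spatial_terms(coords)
        merged = pd.concat([data, spatial], axis=1)
        sets = {"E": list(env_terms), "P": list(pressure_terms),
                "S": list(spatial.columns)}
        return cls(merged, response, family, sets, **kwargs)

    def fit(self) -> "DeviancePartitionResults":
        """Select within each set, fit the seven union models, partition."""
        selected: dict[str, tuple[str, ...]] = {}
        traces: dict[str, SelectionTrace] = {}
        for key, terms in self.sets.items():
            if self.select and terms:
                fit, trace = forward_select(
                    list(terms), self.family, self.response, self.data,
                    vif_cap=self.vif_cap)
                selected[key] = fit.spec.terms
                traces[key] = trace
            else:
                selected[key] = tuple(terms)
                traces[key] = SelectionTrace(final_terms=tuple(terms))

        combos = {
            "E": selected["E"],
            "P": selected["P"],
            "S": selected["S"],
            "EP": selected["E"] + selected["P"],
            "ES": selected["E"] + selected["S"],
            "PS": selected["P"] + selected["S"],
            "EPS": selected["E"] + selected["P"] + selected["S"],
        }
        fits: dict[str, GlmFit] = {}
        D: dict[str, float] = {}
        for label, terms in combos.items():
            fit = fit_glm(GlmSpec(self.family, self.response, terms), self.data)
            if not fit.converged:
                raise RuntimeError(f"sub-model {label} did not converge")
            fits[label] = fit
            D[label] = fit.explained_fraction

        g = (D["E"] + D["P"] + D["S"]
             - D["EP"] - D["ES"] - D["PS"] + D["EPS"])
        fractions = DevianceFractions(
            pure_env=D["EPS"] - D["PS"],
            pure_pressure=D["EPS"] - D["ES"],
            pure_spatial=D["EPS"] - D["EP"],
            env_pressure=D["E"] + D["P"] - D["EP"] - g,
            env_spatial=D["E"] + D["S"] - D["ES"] - g,
            pressure_spatial=D["P"] + D["S"] - D["PS"] - g,
            three_way=g,
            unexplained=1.0 - D["EPS"],
        )
        return DeviancePartitionResults(self, fractions, fits, D,
                                        selected, traces)


class DeviancePartitionResults:
    """Fitted deviance partition: fractions, sub-models, traces, summary."""

    def __init__(self, model: DeviancePartition,
                 fractions: DevianceFractions,
                 submodels: dict[str, GlmFit],
                 explained: dict[str, float],
                 selected: dict[str, tuple[str, ...]],
                 traces: dict[str, SelectionTrace]):
        self.model = model
        self.fractions = fractions
        self.submodels = submodels
        self.explained = explained
        self.selected = selected
        self.traces = traces

    @property
    def negative_shared(self) -> list[str]:
        """Shared components that came out negative (suppression); flagged,
        never truncated."""
        s = self.fractions.to_series()
        shared = ("env_pressure", "env_spatial", "pressure_spatial", "three_way")
        return [k for k in shared if s[k] < 0]

    def to_frame(self) -> pd.DataFrame:
        """One-row report: response, family, 7 deviances, 8 fractions (%)."""
        row: dict[str, object] = {
            "response": self.model.response, "family": self.model.family,
        }
        for label, fit in self.submodels.items():
            row[f"deviance_{label}"] = fit.residual_deviance
        row["null_deviance"] = self.submodels["EPS"].null_deviance
        for name, value in self.fractions.to_series().items():
            row[f"pct_{name}"] = 100.0 * value
        return pd.DataFrame([row])

    def summary(self) -> str:
        s = self.fractions.to_series()
        lines = [
            "Deviance partition",
            "==================",
            f"response: {self.model.response}   family: {self.model.family}   "
            f"n = {self.submodels['EPS'].nobs}",
            f"selected terms  E: {list(self.selected['E'])}",
            f"                P: {list(self.selected['P'])}",
            f"                S: {list(self.selected['S'])}",
            "",
            f"{'component':<22}{'% of null deviance':>20}",
        ]
        pretty = {
            "pure_env": "pure environment (a)",
            "pure_pressure": "pure pressure (b)",
            "pure_spatial": "pure spatial (c)",
            "env_pressure": "env ∩ pressure (d)",
            "env_spatial": "env ∩ spatial (e)",
            "pressure_spatial": "pressure ∩ spatial (f)",
            "three_way": "three-way shared (g)",
            "unexplained": "unexplained (h)",
        }
        for key, label in pretty.items():
            lines.append(f"{label:<22}{100 * s[key]:>19.2f}%")
        lines.append(f"{'sum':<22}{100 * s.sum():>19.2f}%")
        if self.negative_shared:
            lines.append(f"note: negative shared component(s): "
                         f"{self.negative_shared} (suppression; reported "
                         f"as computed)")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar chart of the eight components (matplotlib Axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        s = self.fractions.to_series() * 100
        ax.bar(range(len(s)), s.to_numpy(), color="steelblue")
        ax.set_xticks(range(len(s)), s.index, rotation=45, ha="right")
        ax.set_ylabel("% of null deviance")
        ax.set_title(f"Deviance partition: {self.model.response}")
        ax.axhline(0, color="black", lw=0.8)
        return ax


def partition_deviance(response: str, family: str,
                       sets: Mapping[str, Sequence[str]],
                       data: pd.DataFrame, select: bool = True,
                       vif_cap: float = 3.0) -> DevianceFractions:
    """Functional wrapper: fit the partition, return only the fractions."""
    model = DeviancePartition(data, response, family, sets,
                              select=select, vif_cap=vif_cap)
    return model.fit().fractions
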