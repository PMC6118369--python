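"""Array design descriptions: probe -> probeset -> gene mappings.

An :class:`ArrayDesign` describes the layout of a short-oligo expression
array: which probes belong to which probeset, which probesets interrogate a
gene versus measure background (anti-genomic probesets on PM-only designs),
and whether the design carries mismatch (MM) partner probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

PM_ONLY = "pm_only"
PM_MM = "pm_mm"


class DesignError(ValueError):
    """Raised when an array design violates its structural invariants."""


@dataclass
class ArrayDesign:
    """Probe/probeset layout of one array design.

    Parameters
    ----------
    design_id : str
        Identifier of the design (e.g. ``"synthA"``).
    design_kind : str
        ``"pm_only"`` (no mismatch probes, anti-genomic background
        probesets present) or ``"pm_mm"`` (each PM probe has exactly one
        MM partner).
    probes : pandas.DataFrame
        One row per physical probe with columns ``probe_id``,
        ``probeset_id``, ``kind`` (``"pm"`` or ``"mm"``) and ``pair_id``
        (shared by a PM probe and its MM partner; equals ``probe_id`` for
        PM-only designs).
    probesets : pandas.DataFrame
        Indexed by ``probeset_id`` with columns ``gene_symbol`` (``None``
        for anti-genomic probesets), ``is_antigenomic`` (bool) and
        ``n_probes`` (number of PM probes).
    """

    design_id: str
    design_kind: str
    probes: pd.DataFrame
    probesets: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.design_kind not in (PM_ONLY, PM_MM):
            raise DesignError(f"unknown design_kind {self.design_kind!r}")
        probes = self.probes
        required = {"probe_id", "probeset_id", "kind", "pair_id"}
        if not required.issubset(probes.columns):
            raise DesignError(f"probes table must have columns {sorted(required)}")
        if probes["probe_id"].duplicated().any():
            dup = probes.loc[probes["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise DesignError(f"duplicate probe_id {dup!r}")
        ps = self.probesets
        for col in ("gene_symbol", "is_antigenomic", "n_probes"):
            if col not in ps.columns:
                raise DesignError(f"probesets table missing column {col!r}")
        unknown = set(probes["probeset_id"]) - set(ps.index)
        if unknown:
            raise DesignError(f"probes reference unknown probesets: {sorted(unknown)[:3]}")
        ag = ps["is_antigenomic"]
        if ps.loc[ag, "gene_symbol"].notna().any():
            raise DesignError("anti-genomic probesets must have null gene_symbol")
        if (ps["n_probes"] < 1).any():
            raise DesignError("every probeset needs n_probes >= 1")
        pm = probes[probes["kind"] == "pm"]
        counts = pm.groupby("probeset_id").size()
        mismatch = counts.reindex(ps.index, fill_value=0) != ps["n_probes"]
        if mismatch.any():
            bad = ps.index[mismatch][0]
            raise DesignError(f"probeset {bad!r}: n_probes does not match mapped PM probes")
        if self.design_kind == PM_MM:
            mm = probes[probes["kind"] == "mm"]
            if not pm["pair_id"].is_unique or set(pm["pair_id"]) != set(mm["pair_id"]):
                raise DesignError("pm_mm design requires a 1:1 PM/MM pairing via pair_id")
            if ag.any():
                raise DesignError("pm_mm designs carry no anti-genomic probesets")
        else:
            if (probes["kind"] == "mm").any():
                raise DesignError("pm_only design cannot contain MM probes")

    # -- convenience accessors -------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.probes["probe_id"])

    @property
    def pm_probes(self) -> pd.DataFrame:
        return self.probes[self.probes["kind"] == "pm"]

    @property
    def genomic_probesets(self) -> pd.Index:
        return self.probesets.index[~self.probesets["is_antigenomic"]]

    @property
    def antigenomic_probesets(self) -> pd.Index:
        return self.probesets.index[self.probesets["is_antigenomic"]]

    def gene_of(self) -> pd.Series:
        """gene_symbol per probeset (NaN for anti-genomic/unannotated)."""
        return self.probesets["gene_symbol"]

    def probeset_of_probe(self) -> pd.Series:
        """probeset_id indexed by probe_id (PM probes only)."""
        pm = self.pm_probes
        return pd.Series(pm["probeset_id"].values, index=pm["probe_id"].values)

    def mm_partner(self) -> pd.Series:
        """MM probe_id indexed by PM probe_id (pm_mm designs only)."""
        if self.design_kind != PM_MM:
            raise DesignError("mm_partner() only defined for pm_mm designs")
        probes = self.probes
        pm = probes[probes["kind"] == "pm"].set_index("pair_id")["probe_id"]
        mm = probes[probes["kind"] == "mm"].set_index("pair_id")["probe_id"]
        return pd.Series(mm.reindex(pm.index).values, index=pm.values)
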