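"""File formats and run configuration.

All matrices travel as TSV with a mandatory header row; expression
matrices additionally carry a ``#scale=linear|log2`` comment line so a
file is self-describing about the scale of its values.  Gene modules use
a weighted GMT dialect::

    module_id<TAB>description<TAB>GENE:+1<TAB>GENE:-1 ...

Gene symbols are opaque, case-sensitive strings throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .design import ArrayDesign
from .modules import GeneModule


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ProbeMatrix:
    """Linear-scale probe intensities (probes x samples) for one design."""

    design_id: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() <= 0).any():
            bad = self.values.index[(self.values <= 0).any(axis=1)][0]
            raise FormatError(f"non-positive intensity in probe row {bad!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate probe row {dup!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def validate_against(self, design: ArrayDesign) -> None:
        want = set(design.probe_ids)
        have = set(self.values.index)
        if have != want:
            missing = sorted(want - have)[:3]
            extra = sorted(have - want)[:3]
            raise FormatError(
                f"probe rows do not match design {design.design_id!r}: "
                f"missing {missing}, unknown {extra}"
            )


@dataclass
class ExpressionMatrix:
    """Log2-scale expression (probeset- or gene-level features x samples)."""

    level: str  # 'probeset' | 'gene'
    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.level not in ("probeset", "gene"):
            raise FormatError(f"unknown expression level {self.level!r}")
        if self.scale not in ("linear", "log2"):
            raise FormatError(f"unknown scale {self.scale!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PhenotypeTable:
    """Per-sample ER/HER2 status and intrinsic subtype labels."""

    table: pd.DataFrame  # index sample_id; er_status, her2_status, subtype

    def __post_init__(self) -> None:
        self.table.index.name = "sample_id"
        for col in ("er_status", "her2_status", "subtype"):
            if col not in self.table.columns:
                raise FormatError(f"phenotype table missing column {col!r}")
        for col in ("er_status", "her2_status"):
            bad = set(self.table[col]) - {"pos", "neg"}
            if bad:
                raise FormatError(f"{col} must be pos/neg, got {sorted(bad)}")

    def status(self, marker: str) -> pd.Series:
        marker = marker.upper()
        if marker not in ("ER", "HER2"):
            raise ValueError(f"unknown marker {marker!r}")
        col = "er_status" if marker == "ER" else "her2_status"
        return self.table[col]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Thresholds and knobs shared across pipeline stages.

    Defaults follow the analysis conventions: detection at the 5%
    significance level, PVAC cutoff at the 0.95 quantile of negative
    probeset scores, module reproducibility at Spearman rho > 0.8,
    module-subset validity at rho >= 0.9 against the full module on the
    reference dataset, and de-novo gene selection at |linear fold
    change| > 2 with Welch p < 0.05.
    """

    seed: int = 1
    alpha_detection: float = 0.05
    pvac_negative_quantile: float = 0.95
    rho_reproducible: float = 0.8
    rho_subset_valid: float = 0.9
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    min_module_size: int = 2
    tau: float = 0.015
    out_dir: str = "ffconcord_out"
    log_file: str | None = None

    def __post_init__(self) -> None:
        for name in ("alpha_detection", "pvac_negative_quantile", "p_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.fc_threshold <= 1:
            raise ValueError(f"fc_threshold must exceed 1, got {self.fc_threshold}")
        if self.min_module_size < 2:
            raise ValueError(
                f"min_module_size must be >= 2, got {self.min_module_size}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------


def read_probe_matrix(path: str | Path, design: ArrayDesign) -> ProbeMatrix:
    """Read a linear-scale probe x sample TSV aligned to *design*.

    The first column must be ``probe_id``; remaining header fields are
    sample ids.  Rows are re-ordered to the design's probe order; missing
    or unknown probes, duplicates and non-positive values are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", float_precision="round_trip")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate probe row {dup!r} in {path}")
    m = ProbeMatrix(design_id=design.design_id, values=df)
    m.validate_against(design)
    m.values = df.loc[design.probe_ids]
    return m


def write_probe_matrix(path: str | Path, m: ProbeMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("#scale=linear\n")
        m.values.to_csv(fh, sep="\t", index_label="probe_id")


def read_expression_matrix(path: str | Path, level: str = "gene") -> ExpressionMatrix:
    """Read a feature x sample expression TSV; a ``#scale=`` line is enforced."""
    scale = None
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#scale="):
        scale = first.split("=", 1)[1]
    if scale not in ("linear", "log2"):
        raise FormatError(f"{path}: missing or invalid '#scale=' header line")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", float_precision="round_trip")
    return ExpressionMatrix(level=level, values=df, scale=scale)


def write_expression_matrix(path: str | Path, e: ExpressionMatrix) -> None:
    with open(path, "w") as fh:
        fh.write(f"#scale={e.scale}\n")
        e.values.to_csv(fh, sep="\t", index_label=e.level)


def read_phenotype(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return PhenotypeTable(table=df)


def write_phenotype(path: str | Path, p: PhenotypeTable) -> None:
    p.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# weighted GMT
# ---------------------------------------------------------------------------


def read_modules_wgmt(path: str | Path) -> list[GeneModule]:
    """Parse a weighted-GMT file into a list of gene modules.

    Each non-empty line is ``module_id TAB description TAB gene:+1 ...``;
    weights must be ``+1`` or ``-1`` and genes may not repeat within a
    module.  Module order is preserved.
    """
    out: list[GeneModule] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected at least 3 tab fields")
            module_id, description = fields[0], fields[1]
            genes: list[tuple[str, int]] = []
            seen: set[str] = set()
            for tok in fields[2:]:
                if not tok:
                    continue
                gene, _, w = tok.rpartition(":")
                if not gene or w not in ("+1", "-1", "1"):
                    raise FormatError(
                        f"{path}:{lineno}: bad gene token {tok!r} (weight must be +1/-1)"
                    )
                if gene in seen:
                    raise FormatError(f"{path}:{lineno}: duplicate gene {gene!r}")
                seen.add(gene)
                genes.append((gene, 1 if w in ("+1", "1") else -1))
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty module {module_id!r}")
            out.append(
                GeneModule(module_id=module_id, genes=genes, description=description)
            )
    return out


def write_modules_wgmt(path: str | Path, modules: Iterable[GeneModule]) -> None:
    with open(path, "w") as fh:
        for mod in modules:
            toks = [f"{g}:{'+1' if w > 0 else '-1'}" for g, w in mod.genes]
            fh.write("\t".join([mod.module_id, mod.description or "na", *toks]) + "\n")
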