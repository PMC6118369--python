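"""Synthetic matched FF/FFPE probe-level experiments with known ground truth.

The generator emulates a matched study design: eight breast tumors, two
per intrinsic subtype (Luminal-A ER+/HER2-, Luminal-B ER+/HER2+,
HER2-amplified ER-/HER2+, Triple-Negative ER-/HER2-), profiled as five
matched datasets — two fresh-frozen and three FFPE — across two array
designs: design A is a PM-MM array (mismatch partner probes, no
anti-genomic probesets) and design B a PM-only array carrying
anti-genomic background probesets.

Intensity model (linear scale), for probe ``p`` of gene ``g``, sample
``s``, dataset ``k``::

    I = 2 ** (mu_gs + log2 r_gk + a_p + b_pk + eps) + B

where ``mu_gs`` is the true log2 expression (only for expressed,
coherent probesets), ``r_gk`` a per-gene retention factor modelling RNA
degradation (``r = 1`` in FF datasets; ``r ~ Beta(kappa*(1-d)+1,
kappa*d+1)`` in an FFPE dataset of severity ``d``), ``a_p`` a per-probe
affinity shared across datasets of a design, ``b_pk`` a per-dataset kit
perturbation of that affinity, ``eps`` measurement noise, and ``B`` an
additive lognormal optical/cross-hybridization background shared by
genomic, anti-genomic and MM probes.  Anti-genomic probesets,
non-expressed genes, incoherent probesets and MM probes emit background
only.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import PM_MM, PM_ONLY, ArrayDesign
from .io import PhenotypeTable, ProbeMatrix

SUBTYPE_STATUS = {
    "LumA": ("pos", "neg"),
    "LumB": ("pos", "pos"),
    "HER2": ("neg", "pos"),
    "TN": ("neg", "neg"),
}

#: dataset id -> (design label, is_ffpe); mirrors a gold-standard FF PM-MM
#: dataset, its FFPE counterpart, and a PM-only trio (FF + two FFPE kits).
DATASET_LAYOUT: dict[str, tuple[str, bool]] = {
    "ff.A": ("A", False),
    "ffpe.A": ("A", True),
    "ff.B": ("B", False),
    "ffpe.B1": ("B", True),
    "ffpe.B2": ("B", True),
}


def _substream(seed: int, *tags: str) -> np.random.Generator:
    """Named, order-independent child stream of the master seed."""
    digest = hashlib.sha256("/".join(tags).encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *words])


@dataclass
class SimulationConfig:
    """Parameters of the stated synthetic world.

    Degradation severities default to a near-destroyed polyA-kit FFPE
    dataset (``ffpe.A``: 0.8) and two moderately degraded FFPE-kit
    datasets (``ffpe.B1``/``ffpe.B2``: 0.5).
    """

    n_samples: int = 8
    subtype_design: tuple[tuple[str, int], ...] = (
        ("LumA", 2),
        ("LumB", 2),
        ("HER2", 2),
        ("TN", 2),
    )
    n_genes: int = 2000
    probes_per_probeset: int = 11
    n_antigenomic: int = 23
    frac_expressed: float = 0.6
    degradation_severity: dict[str, float] = field(
        default_factory=lambda: {"ffpe.A": 0.8, "ffpe.B1": 0.5, "ffpe.B2": 0.5}
    )
    retention_shape: float = 10.0
    probe_affinity_sd: float = 0.3
    noise_sd: float = 0.25
    background_mean: float = 6.0
    background_sd: float = 0.5
    background_mean_override: dict[str, float] = field(default_factory=dict)
    kit_effect_sd: float = 0.2
    de_log2fc: float = 2.0
    n_de_genes: int = 50
    expressed_mean_low: float = 6.5
    expressed_mean_high: float = 12.0
    biological_sd: float = 1.0
    sample_retention_sd: float = 1.0
    degradation_probe_noise_sd: float = 0.5
    shared_degradation: bool = True
    frac_incoherent_probesets: float = 0.0
    duplicate_probeset_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for k, d in self.degradation_severity.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"severity for {k!r} must lie in [0,1], got {d}")
        if not 0.0 < self.frac_expressed < 1.0:
            raise ValueError("frac_expressed must lie in (0,1)")
        if 2 * self.n_de_genes >= self.n_genes * self.frac_expressed:
            raise ValueError("too many DE genes for the expressed gene pool")
        if sum(n for _, n in self.subtype_design) != self.n_samples:
            raise ValueError("subtype_design must sum to n_samples")

    @property
    def sample_ids(self) -> list[str]:
        return [f"s{i + 1}" for i in range(self.n_samples)]

    def subtypes(self) -> list[str]:
        out: list[str] = []
        for name, n in self.subtype_design:
            out.extend([name] * n)
        return out


@dataclass
class GroundTruth:
    """Simulation truth, sufficient to audit every downstream stage."""

    gene_means: pd.DataFrame  # gene x sample true log2 expression (mu_gs)
    base_means: pd.Series  # neutral per-gene mean (no subtype effects, no bio noise)
    expressed: pd.Series  # bool per gene
    er_de: pd.Series  # {-1, 0, +1} per gene: sign of the planted ER effect
    her2_de: pd.Series
    retention: pd.DataFrame  # gene x dataset retention r_gk (1 for FF)
    probeset_coherent: dict[str, pd.Series]  # per design label
    designs: dict[str, ArrayDesign]
    dataset_design: dict[str, str]  # dataset id -> design label
    background_mean: float
    phenotype: PhenotypeTable


@dataclass
class SimulatedExperiment:
    """Bundle returned by :func:`simulate_matched_experiment`."""

    datasets: dict[str, ProbeMatrix]
    truth: GroundTruth
    phenotype: PhenotypeTable
    designs: dict[str, ArrayDesign]
    manifest: pd.DataFrame


def make_array_design(cfg: SimulationConfig, design_kind: str, design_id: str | None = None) -> ArrayDesign:
    """Build a synthetic array design: genomic probesets 1:1 with genes.

    PM-only designs add ``cfg.n_antigenomic`` anti-genomic probesets; PM-MM
    designs add an MM partner row per PM probe instead.  With
    ``duplicate_probeset_frac > 0`` an extra probeset is added for that
    leading fraction of genes, exercising max-variance probeset selection.
    """
    if design_kind not in (PM_ONLY, PM_MM):
        raise ValueError(f"unknown design_kind {design_kind!r}")
    design_id = design_id or ("synthB" if design_kind == PM_ONLY else "synthA")
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    ps_rows: list[tuple[str, object, bool]] = [(f"ps_{g}", g, False) for g in genes]
    n_dup = int(round(cfg.duplicate_probeset_frac * cfg.n_genes))
    ps_rows += [(f"ps_{g}_b", g, False) for g in genes[:n_dup]]
    if design_kind == PM_ONLY:
        ps_rows += [(f"ag_{i + 1:03d}", None, True) for i in range(cfg.n_antigenomic)]
    probe_rows: list[tuple[str, str, str, str]] = []
    for ps_id, _, _ in ps_rows:
        for j in range(cfg.probes_per_probeset):
            pid = f"{ps_id}_p{j + 1:02d}"
            probe_rows.append((pid, ps_id, "pm", pid))
            if design_kind == PM_MM:
                probe_rows.append((f"{pid}m", ps_id, "mm", pid))
    probes = pd.DataFrame(probe_rows, columns=["probe_id", "probeset_id", "kind", "pair_id"])
    probesets = pd.DataFrame(
        {
            "gene_symbol": [g for _, g, _ in ps_rows],
            "is_antigenomic": [a for _, _, a in ps_rows],
            "n_probes": cfg.probes_per_probeset,
        },
        index=pd.Index([p for p, _, _ in ps_rows], name="probeset_id"),
    )
    return ArrayDesign(design_id=design_id, design_kind=design_kind, probes=probes, probesets=probesets)


def _make_phenotype(cfg: SimulationConfig) -> PhenotypeTable:
    subtypes = cfg.subtypes()
    rows = {
        sid: {
            "er_status": SUBTYPE_STATUS[st][0],
            "her2_status": SUBTYPE_STATUS[st][1],
            "subtype": st,
        }
        for sid, st in zip(cfg.sample_ids, subtypes)
    }
    return PhenotypeTable(table=pd.DataFrame.from_dict(rows, orient="index"))


def _make_gene_truth(
    cfg: SimulationConfig, pheno: PhenotypeTable
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.Series, pd.Series]:
    """Per-gene truth: base means, inter-tumor variation and planted DE.

    Expressed genes get a base log2 mean Uniform(low, high) plus a
    per-gene, per-tumor biological deviation ``N(0, biological_sd^2)``
    shared by every dataset (the same eight tumors are profiled
    throughout) — this inter-tumor variance is what downstream gene and
    module correlations measure.  Planted ER/HER2 effects shift
    marker-positive samples by ``+/- de_log2fc``.
    """
    rng = _substream(cfg.seed, "truth")
    genes = pd.Index([f"G{i + 1:04d}" for i in range(cfg.n_genes)], name="gene")
    n_expr = int(round(cfg.frac_expressed * cfg.n_genes))
    order = rng.permutation(cfg.n_genes)
    expressed = pd.Series(False, index=genes)
    expressed.iloc[order[:n_expr]] = True
    base = pd.Series(0.0, index=genes)
    base.loc[expressed] = rng.uniform(cfg.expressed_mean_low, cfg.expressed_mean_high, n_expr)
    expr_idx = order[:n_expr]
    de_pick = expr_idx[: 2 * cfg.n_de_genes]
    er_de = pd.Series(0, index=genes)
    her2_de = pd.Series(0, index=genes)
    signs = np.where(np.arange(cfg.n_de_genes) % 2 == 0, 1, -1)
    er_de.iloc[de_pick[: cfg.n_de_genes]] = signs
    her2_de.iloc[de_pick[cfg.n_de_genes :]] = signs
    er_pos = (pheno.table["er_status"] == "pos").to_numpy()
    her2_pos = (pheno.table["her2_status"] == "pos").to_numpy()
    mu = np.tile(base.to_numpy()[:, None], (1, cfg.n_samples))
    mu += rng.normal(0.0, cfg.biological_sd, mu.shape)
    mu += np.outer(er_de.to_numpy(), er_pos) * cfg.de_log2fc
    mu += np.outer(her2_de.to_numpy(), her2_pos) * cfg.de_log2fc
    mu[~expressed.to_numpy()] = 0.0
    gene_means = pd.DataFrame(mu, index=genes, columns=cfg.sample_ids)
    return gene_means, base, expressed, er_de, her2_de


def simulate_matched_experiment(cfg: SimulationConfig) -> SimulatedExperiment:
    """Simulate the five matched datasets plus ground truth and phenotype.

    The master seed spawns named substreams per dataset and per design,
    so adding or re-ordering datasets does not perturb the draws of the
    others.  Rerunning with the same config is bit-identical.
    """
    pheno = _make_phenotype(cfg)
    gene_means, base_means, expressed, er_de, her2_de = _make_gene_truth(cfg, pheno)
    designs = {
        "A": make_array_design(cfg, PM_MM, "synthA"),
        "B": make_array_design(cfg, PM_ONLY, "synthB"),
    }

    # per-design probe affinities and incoherent-probeset flags
    affinities: dict[str, pd.Series] = {}
    coherent: dict[str, pd.Series] = {}
    frag_probe: dict[str, np.ndarray] = {}
    for label, design in designs.items():
        rng = _substream(cfg.seed, "design", label)
        pm = design.pm_probes
        affinities[label] = pd.Series(
            rng.normal(0.0, cfg.probe_affinity_sd, len(pm)), index=pm["probe_id"].values
        )
        # fragmentation hits probe target regions unevenly, per sample; the
        # pattern belongs to the tissue RNA, so FFPE datasets sharing a
        # design see the same field (scaled by their own severity)
        frag_probe[label] = _substream(cfg.seed, "fragmentation", label).normal(
            size=(len(pm), cfg.n_samples)
        )
        ps = design.probesets
        genomic = ~ps["is_antigenomic"]
        incoh = pd.Series(False, index=ps.index)
        if cfg.frac_incoherent_probesets > 0:
            gen_ids = ps.index[genomic]
            k = int(round(cfg.frac_incoherent_probesets * len(gen_ids)))
            incoh.loc[rng.choice(gen_ids, size=k, replace=False)] = True
        gene_expressed = ps["gene_symbol"].map(expressed).astype("boolean").fillna(False).astype(bool)
        coherent[label] = genomic & gene_expressed & ~incoh

    retention = pd.DataFrame(1.0, index=gene_means.index, columns=list(DATASET_LAYOUT))
    datasets: dict[str, ProbeMatrix] = {}
    kappa = cfg.retention_shape
    # Degradation lives in the tissue block, not the kit: with
    # shared_degradation the per-gene fragility rank is drawn once and each
    # FFPE dataset maps it through its own Beta quantile function, so the
    # same genes are lost everywhere while every dataset keeps exactly the
    # Beta(kappa*(1-d)+1, kappa*d+1) retention marginal.  On top of the
    # per-gene factor, each block's fixation history perturbs individual
    # gene x sample measurements: a tissue-shared standard-normal field
    # scaled by severity * sample_retention_sd shifts log2 retention
    # (clipped at 0 — degradation never amplifies).  FF datasets see
    # neither effect; FFPE datasets of the same tissue share both, which
    # is what keeps FFPE<->FFPE concordance above FF<->FFPE.
    deg_rng = _substream(cfg.seed, "degradation")
    frag_u = deg_rng.uniform(size=cfg.n_genes)
    frag_z = deg_rng.normal(size=(cfg.n_genes, cfg.n_samples))
    for ds_id, (label, is_ffpe) in DATASET_LAYOUT.items():
        design = designs[label]
        rng = _substream(cfg.seed, "dataset", ds_id)
        d = cfg.degradation_severity.get(ds_id, 0.5) if is_ffpe else 0.0
        if d > 0:
            a, b = kappa * (1.0 - d) + 1.0, kappa * d + 1.0
            if cfg.shared_degradation:
                r = stats.beta.ppf(1.0 - frag_u, a, b)
            else:
                r = rng.beta(a, b, cfg.n_genes)
        else:
            # severity 0 is lossless by definition, for FFPE datasets too
            r = np.ones(cfg.n_genes)
        retention[ds_id] = r
        log2r_gs = np.log2(r)[:, None] + (d * cfg.sample_retention_sd) * frag_z
        log2r_gs = np.minimum(log2r_gs, 0.0)
        log2r_df = pd.DataFrame(log2r_gs, index=gene_means.index, columns=cfg.sample_ids)

        pm = design.pm_probes
        probe_ids = pm["probe_id"].to_numpy()
        ps_of_probe = pm["probeset_id"].to_numpy()
        ps = design.probesets
        gene_of_ps = ps["gene_symbol"]
        probe_gene = pd.Series(ps_of_probe).map(gene_of_ps).to_numpy()
        probe_coherent = pd.Series(ps_of_probe).map(coherent[label]).to_numpy(dtype=bool)

        n_pm, n_s = len(probe_ids), cfg.n_samples
        b_pk = rng.normal(0.0, cfg.kit_effect_sd, n_pm)
        eps = rng.normal(0.0, cfg.noise_sd, (n_pm, n_s))
        if d > 0:
            eps = eps + (d * cfg.degradation_probe_noise_sd) * frag_probe[label]
        bg_mean = cfg.background_mean_override.get(ds_id, cfg.background_mean)
        all_probes = design.probes["probe_id"].to_numpy()
        bg = 2.0 ** rng.normal(bg_mean, cfg.background_sd, (len(all_probes), n_s))
        bg = pd.DataFrame(bg, index=all_probes, columns=cfg.sample_ids)

        signal = np.zeros((n_pm, n_s))
        mask = probe_coherent
        if mask.any():
            mu = gene_means.reindex(pd.Index(probe_gene[mask])).to_numpy()
            log2r = log2r_df.reindex(pd.Index(probe_gene[mask])).to_numpy()
            a = affinities[label].to_numpy()[mask]
            sig = mu + log2r + a[:, None] + b_pk[mask, None] + eps[mask]
            signal[mask] = 2.0**sig
        intens = bg.copy()
        intens.loc[probe_ids] = intens.loc[probe_ids].to_numpy() + signal
        intens = intens.loc[design.probe_ids]
        datasets[ds_id] = ProbeMatrix(design_id=design.design_id, values=intens)

    truth = GroundTruth(
        gene_means=gene_means,
        base_means=base_means,
        expressed=expressed,
        er_de=er_de,
        her2_de=her2_de,
        retention=retention,
        probeset_coherent=coherent,
        designs={d.design_id: d for d in designs.values()},
        dataset_design={k: designs[v[0]].design_id for k, v in DATASET_LAYOUT.items()},
        background_mean=cfg.background_mean,
        phenotype=pheno,
    )
    manifest = pd.DataFrame(
        {
            "dataset_id": list(DATASET_LAYOUT),
            "design_id": [designs[v[0]].design_id for v in DATASET_LAYOUT.values()],
            "preservation": ["ffpe" if v[1] else "ff" for v in DATASET_LAYOUT.values()],
            "severity": [
                cfg.degradation_severity.get(k, 0.5) if v[1] else 0.0
                for k, v in DATASET_LAYOUT.items()
            ],
            "role": ["ref1", "matched", "ref2", "ref3", "matched"],
        }
    ).set_index("dataset_id")
    return SimulatedExperiment(
        datasets=datasets, truth=truth, phenotype=pheno, designs=designs, manifest=manifest
    )


def make_module_collection(
    truth: GroundTruth,
    cfg: SimulationConfig,
    n_random: int = 40,
    size_low: int = 8,
    size_high: int = 25,
    n_controls: int = 5,
) -> "list":
    """Synthetic stand-in for an external gene-module collection.

    Emits ``n_random`` modules of random expressed genes with random +/-1
    weights (labelled ``external_set1``), two planted modules tracking
    the true ER and HER2 programs (weights = planted effect signs), and
    ``n_controls`` all-positive control modules: one "housekeeping"
    module of expressed non-DE genes and absent-signal controls drawn
    from non-expressed genes.
    """
    from .modules import GeneModule

    rng = _substream(cfg.seed, "modules")
    expressed = truth.expressed.index[truth.expressed]
    de_genes = set(truth.er_de.index[truth.er_de != 0]) | set(
        truth.her2_de.index[truth.her2_de != 0]
    )
    out: list[GeneModule] = []
    for i in range(n_random):
        size = int(rng.integers(size_low, size_high + 1))
        genes = rng.choice(expressed, size=size, replace=False)
        weights = rng.choice([1, -1], size=size)
        out.append(
            GeneModule(
                module_id=f"rand{i + 1:03d}",
                genes=list(zip(genes, weights)),
                provenance="external_set1",
            )
        )
    for marker, de in (("ER", truth.er_de), ("HER2", truth.her2_de)):
        genes = [(g, int(s)) for g, s in de[de != 0].items()]
        out.append(
            GeneModule(
                module_id=f"planted_{marker}", genes=genes, provenance="external_set1"
            )
        )
    housekeeping = [g for g in expressed if g not in de_genes]
    hk = rng.choice(housekeeping, size=min(20, len(housekeeping)), replace=False)
    out.append(
        GeneModule(
            module_id="ctrl_housekeeping",
            genes=[(g, 1) for g in hk],
            provenance="control",
        )
    )
    silent = truth.expressed.index[~truth.expressed]
    for i in range(max(0, n_controls - 1)):
        genes = rng.choice(silent, size=min(15, len(silent)), replace=False)
        out.append(
            GeneModule(
                module_id=f"ctrl_absent{i + 1}",
                genes=[(g, 1) for g in genes],
                provenance="control",
            )
        )
    return out


def simulate_validation_cohort(
    cfg: SimulationConfig,
    truth: GroundTruth,
    n_samples: int = 100,
    noise_sd: float = 0.5,
    stream: str = "validation",
):
    """Independent gene-level cohort for signature validation.

    Samples draw ER/HER2 statuses uniformly over the four subtypes and
    gene-level log2 expression directly from the truth means plus
    ``N(0, noise_sd^2)`` noise; non-expressed genes sit at the background
    mean plus noise.  Returns ``(ExpressionMatrix, PhenotypeTable)``.
    """
    from .io import ExpressionMatrix

    rng = _substream(cfg.seed, stream)
    subtypes = [list(SUBTYPE_STATUS)[i % 4] for i in range(n_samples)]
    sample_ids = [f"v{i + 1}" for i in range(n_samples)]
    rows = {
        sid: {
            "er_status": SUBTYPE_STATUS[st][0],
            "her2_status": SUBTYPE_STATUS[st][1],
            "subtype": st,
        }
        for sid, st in zip(sample_ids, subtypes)
    }
    pheno = PhenotypeTable(table=pd.DataFrame.from_dict(rows, orient="index"))
    genes = truth.expressed.index
    base = truth.base_means.copy()
    base[~truth.expressed] = cfg.background_mean
    er_pos = np.array([SUBTYPE_STATUS[st][0] == "pos" for st in subtypes])
    her2_pos = np.array([SUBTYPE_STATUS[st][1] == "pos" for st in subtypes])
    mu = np.tile(base.to_numpy()[:, None], (1, n_samples))
    mu += rng.normal(0.0, cfg.biological_sd, mu.shape)
    mu += np.outer(truth.er_de.to_numpy(), er_pos) * cfg.de_log2fc
    mu += np.outer(truth.her2_de.to_numpy(), her2_pos) * cfg.de_log2fc
    vals = mu + rng.normal(0.0, noise_sd, mu.shape)
    vals = np.maximum(vals, 0.01)  # module scores need positive log2 values
    expr = ExpressionMatrix(
        level="gene", values=pd.DataFrame(vals, index=genes, columns=sample_ids)
    )
    return expr, pheno


def truth_present(truth: GroundTruth, dataset_id: str) -> pd.DataFrame:
    """Expected Present flags per probeset x sample for one dataset.

    A probeset is expected Present when its gene is expressed, the
    probeset is coherent (follows its gene), and the retained linear
    signal ``r_gk * 2**mu_gs`` exceeds the background median
    ``2**background_mean``.  Anti-genomic probesets are never expected
    Present.
    """
    if dataset_id not in truth.dataset_design:
        raise KeyError(f"unknown dataset {dataset_id!r}")
    design = truth.designs[truth.dataset_design[dataset_id]]
    label = "A" if design.design_kind == PM_MM else "B"
    ps = design.probesets
    r = truth.retention[dataset_id]
    lin = truth.gene_means.apply(lambda col: r * 2.0**col)
    above = lin.gt(2.0**truth.background_mean)
    above = above.mul(truth.expressed, axis=0)
    flags = pd.DataFrame(False, index=ps.index, columns=truth.gene_means.columns)
    genomic = ps.index[~ps["is_antigenomic"]]
    gene_of = ps.loc[genomic, "gene_symbol"]
    flags.loc[genomic] = above.reindex(gene_of).to_numpy()
    flags.loc[~truth.probeset_coherent[label].reindex(ps.index, fill_value=False)] = False
    return flags
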