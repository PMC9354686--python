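"""Synthetic paired gene/miR count data with planted, fully known structure.

The generator emulates the statistical features the pipeline relies on:

* negative-binomial raw counts with per-sample library-size variation
  (counts ~ NB(mu * lib_s, alpha), library factors LogNormal(0, cv));
* stage-wise differential expression: an effect of log2fc e planted on a
  contiguous contrast (ref, test) multiplies the feature's mean by 2^e in
  the test phenotype *and all later phenotypes* (expression levels are
  cumulative along progression);
* coupled miR-gene pairs: in each active phenotype a per-sample latent
  z ~ N(0,1) multiplies the gene mean by exp(l_g*z - l_g^2/2) and the miR
  mean by exp(sign*l_m*z - l_m^2/2).  Each feature's loading is calibrated
  from its own log-scale noise variance s_f^2 = ln(1 + alpha + 1/mu) as
  l_f^2 = rho/(1-rho) * s_f^2, which makes the latent-to-total variance
  ratio rho/( rho + (1-rho) ) on both sides and hence the induced log-scale
  correlation exactly rho even when the two endpoints' noise levels differ.
  All couplings of one miR that are active in the same phenotype share a
  single latent (a regulon), so multiply-coupled miRs keep variance
  inflation l_m^2 rather than accumulating one factor per target.  The
  -l^2/2 terms keep every marginal mean unchanged;
* genomic coordinates: every annotated feature gets a chromosome, cytoband
  and 1-based start/end; a configured fraction of the coupled pairs is
  placed in the same cytoband (deterministic count, rounded).

Everything planted is returned in a :class:`SyntheticTruth` table, so each
downstream stage of the pipeline can be scored against ground truth.
A fixed seed makes the output byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .diffexpr import Contrast, contiguous_contrasts
from .io_formats import (
    STAGE_ORDER,
    ExpressionMatrix,
    FeatureAnnotation,
    SampleTable,
)


@dataclass(frozen=True)
class DEEffect:
    """A planted multiplicative effect on one contiguous contrast."""

    contrast: str  # label, e.g. "NT-I"
    feature_id: str
    kind: str  # "gene" | "miR"
    log2fc: float

    def __post_init__(self):
        Contrast.from_label(self.contrast)
        if self.log2fc == 0:
            raise ValueError("planted effect size must be nonzero")
        if self.kind not in ("gene", "miR"):
            raise ValueError(f"bad kind {self.kind!r}")


@dataclass(frozen=True)
class Coupling:
    """A planted dependent miR-gene pair.

    ``sign`` -1 couples the pair negatively (anti-correlated, canonical
    repression), +1 positively.  ``category`` tags the pair's role in the
    study design: "stage" (DE endpoints keyed to one contrast, expected in
    that stage's canonical network), "tumor_only" (active in all four
    stages, absent NT) or "positive" (distractor, filtered out by sign).
    """

    mir_id: str
    gene_id: str
    sign: int
    rho: float
    active_phenotypes: tuple[str, ...]
    category: str = "stage"
    stage: str | None = None

    def __post_init__(self):
        if self.sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (0, 1)")
        for p in self.active_phenotypes:
            if p not in STAGE_ORDER:
                raise ValueError(f"unknown phenotype {p!r}")


@dataclass(frozen=True)
class AnnotationPlan:
    chromosomes: tuple[str, ...] = tuple(str(i) for i in range(1, 9))
    bands: tuple[str, ...] = ("p12", "p11", "q11", "q12", "q21", "q22")
    same_cytoband_fraction: float = 0.5
    band_span: int = 10_000_000


@dataclass
class SimulationConfig:
    """Full description of one synthetic study; seed fixed => identical bytes."""

    n_genes: int = 300
    n_mirs: int = 50
    samples_per_phenotype: dict = field(
        default_factory=lambda: {"NT": 40, "I": 60, "II": 40, "III": 40, "IV": 40}
    )
    baseline_log10_range: tuple[float, float] = (1.5, 3.0)
    dispersion: float = 0.1
    dispersion_overrides: dict = field(default_factory=dict)
    baseline_log10_overrides: dict = field(default_factory=dict)
    library_size_cv: float = 0.25
    de_plan: list = field(default_factory=list)
    coupling_plan: list = field(default_factory=list)
    annotation_plan: AnnotationPlan = field(default_factory=AnnotationPlan)
    unannotated_features: tuple[str, ...] = ()
    seed: int = 0

    # -- id helpers -----------------------------------------------------------
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    def mir_ids(self) -> list[str]:
        return [f"miR-{i:02d}" for i in range(1, self.n_mirs + 1)]

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_mirs <= 0:
            raise ValueError("feature counts must be positive")
        for phen, n in self.samples_per_phenotype.items():
            if phen not in STAGE_ORDER or n <= 0:
                raise ValueError(f"bad sample plan entry {phen!r}: {n}")
        if set(self.samples_per_phenotype) != set(STAGE_ORDER):
            raise ValueError("sample plan must cover all five phenotypes")
        genes, mirs = set(self.gene_ids()), set(self.mir_ids())
        for eff in self.de_plan:
            pool = genes if eff.kind == "gene" else mirs
            if eff.feature_id not in pool:
                raise ValueError(f"DE plan references unknown feature {eff.feature_id!r}")
        seen_pairs = set()
        for cp in self.coupling_plan:
            if cp.mir_id not in mirs or cp.gene_id not in genes:
                raise ValueError(
                    f"coupling references unknown features ({cp.mir_id!r}, {cp.gene_id!r})"
                )
            if (cp.mir_id, cp.gene_id) in seen_pairs:
                raise ValueError(f"duplicate coupling ({cp.mir_id}, {cp.gene_id})")
            seen_pairs.add((cp.mir_id, cp.gene_id))
        n_de = len({(e.kind, e.feature_id) for e in self.de_plan})
        if n_de > self.n_genes + self.n_mirs:
            raise ValueError("more DE features than features: infeasible plan")


@dataclass
class SyntheticTruth:
    """Everything that was planted, for scoring the pipeline against."""

    de_effects: pd.DataFrame  # kind, feature_id, contrast, log2fc
    couplings: pd.DataFrame  # mir_id, gene_id, sign, rho, active, category, stage, same_cytoband
    annotation: FeatureAnnotation
    persistent_mir: str | None = None

    def coupled_pairs_for_stage(self, stage: str) -> frozenset[tuple[str, str]]:
        """Negative couplings with DE endpoints keyed to the given stage."""
        sub = self.couplings[
            (self.couplings["category"] == "stage")
            & (self.couplings["stage"] == stage)
            & (self.couplings["sign"] == -1)
        ]
        return frozenset(zip(sub["mir_id"], sub["gene_id"]))

    def tumor_only_pairs(self) -> frozenset[tuple[str, str]]:
        sub = self.couplings[self.couplings["category"] == "tumor_only"]
        return frozenset(zip(sub["mir_id"], sub["gene_id"]))

    def persistent_targets(self) -> dict[str, set[str]]:
        """stage -> planted target genes of the persistent miR."""
        out: dict[str, set[str]] = {s: set() for s in STAGE_ORDER[1:]}
        if self.persistent_mir is None:
            return out
        sub = self.couplings[
            (self.couplings["mir_id"] == self.persistent_mir)
            & (self.couplings["category"] == "stage")
        ]
        for _, row in sub.iterrows():
            out[row["stage"]].add(row["gene_id"])
        return out

    def planted_log2fc(self, kind: str, feature_id: str, contrast_label: str) -> float:
        sub = self.de_effects[
            (self.de_effects["kind"] == kind)
            & (self.de_effects["feature_id"] == feature_id)
            & (self.de_effects["contrast"] == contrast_label)
        ]
        return float(sub["log2fc"].sum())


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _baselines(ids: list[str], cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.baseline_log10_range
    base = 10.0 ** rng.uniform(lo, hi, size=len(ids))
    for i, fid in enumerate(ids):
        if fid in cfg.baseline_log10_overrides:
            ov = cfg.baseline_log10_overrides[fid]
            if isinstance(ov, tuple):
                base[i] = 10.0 ** rng.uniform(*ov)
            else:
                base[i] = 10.0 ** float(ov)
    return base


def _stage_levels(ids: list[str], kind: str, cfg: SimulationConfig) -> np.ndarray:
    """Cumulative log2 expression level per feature per phenotype."""
    index = {fid: i for i, fid in enumerate(ids)}
    levels = np.zeros((len(ids), len(STAGE_ORDER)))
    transition = {c.label: j for j, c in enumerate(contiguous_contrasts(), start=1)}
    for eff in cfg.de_plan:
        if eff.kind != kind:
            continue
        j = transition[eff.contrast]
        levels[index[eff.feature_id], j:] += eff.log2fc
    return levels


def _dispersions(ids: list[str], cfg: SimulationConfig) -> np.ndarray:
    alpha = np.full(len(ids), float(cfg.dispersion))
    for i, fid in enumerate(ids):
        if fid in cfg.dispersion_overrides:
            alpha[i] = float(cfg.dispersion_overrides[fid])
    return alpha


def generate(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleTable, FeatureAnnotation, SyntheticTruth]:
    """Draw one synthetic study: paired count matrices, sample table,
    annotation and the truth tables."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = config.gene_ids()
    mir_ids = config.mir_ids()
    gi = {g: i for i, g in enumerate(gene_ids)}
    mi_ = {m: i for i, m in enumerate(mir_ids)}

    # samples, in fixed phenotype-block order
    sample_ids: list[str] = []
    stages: dict[str, str] = {}
    phen_of: list[str] = []
    for phen in STAGE_ORDER:
        for j in range(config.samples_per_phenotype[phen]):
            sid = f"{phen}_{j:03d}"
            sample_ids.append(sid)
            stages[sid] = phen
            phen_of.append(phen)
    n_samples = len(sample_ids)
    phen_idx = np.array([STAGE_ORDER.index(p) for p in phen_of])

    gene_base = _baselines(gene_ids, config, rng)
    mir_base = _baselines(mir_ids, config, rng)
    gene_levels = _stage_levels(gene_ids, "gene", config)
    mir_levels = _stage_levels(mir_ids, "miR", config)
    gene_alpha = _dispersions(gene_ids, config)
    mir_alpha = _dispersions(mir_ids, config)

    lib = rng.lognormal(mean=0.0, sigma=config.library_size_cv, size=n_samples)

    # mean matrices before coupling
    gene_mu = gene_base[:, None] * 2.0 ** gene_levels[:, phen_idx] * lib[None, :]
    mir_mu = mir_base[:, None] * 2.0 ** mir_levels[:, phen_idx] * lib[None, :]

    # latent-factor coupling, mean preserving; one latent per (miR,
    # phenotype) group so a multiply-targeted miR forms a coherent regulon
    groups: dict[tuple[int, int], list[Coupling]] = {}
    for cp in config.coupling_plan:
        for phen in cp.active_phenotypes:
            groups.setdefault((mi_[cp.mir_id], STAGE_ORDER.index(phen)), []).append(cp)
    for (midx, p), cps in sorted(groups.items()):
        signs = {cp.sign for cp in cps}
        rhos = {cp.rho for cp in cps}
        if len(signs) > 1 or len(rhos) > 1:
            raise ValueError(
                f"couplings of {mir_ids[midx]} active in {STAGE_ORDER[p]} must "
                "share one sign and strength (they share a latent factor)"
            )
        sign, rho = signs.pop(), rhos.pop()
        cols = np.flatnonzero(phen_idx == p)
        z = rng.standard_normal(cols.size)
        mu_m = mir_base[midx] * 2.0 ** mir_levels[midx, p]
        l_m = np.sqrt(rho / (1.0 - rho) * np.log1p(mir_alpha[midx] + 1.0 / mu_m))
        mir_mu[midx, cols] *= np.exp(sign * l_m * z - l_m**2 / 2.0)
        for cp in cps:
            gidx = gi[cp.gene_id]
            mu_g = gene_base[gidx] * 2.0 ** gene_levels[gidx, p]
            l_g = np.sqrt(rho / (1.0 - rho) * np.log1p(gene_alpha[gidx] + 1.0 / mu_g))
            gene_mu[gidx, cols] *= np.exp(l_g * z - l_g**2 / 2.0)

    def _nb_draw(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
        counts = np.empty_like(mu, dtype=np.int64)
        for i in range(mu.shape[0]):
            if alpha[i] <= 0:
                counts[i] = rng.poisson(mu[i])
            else:
                lam = rng.gamma(shape=1.0 / alpha[i], scale=mu[i] * alpha[i])
                counts[i] = rng.poisson(lam)
        return counts

    gene_counts = _nb_draw(gene_mu, gene_alpha)
    mir_counts = _nb_draw(mir_mu, mir_alpha)

    gene_mat = ExpressionMatrix(
        pd.DataFrame(gene_counts, index=pd.Index(gene_ids, name="id"), columns=sample_ids),
        "gene", "raw counts",
    )
    mir_mat = ExpressionMatrix(
        pd.DataFrame(mir_counts, index=pd.Index(mir_ids, name="id"), columns=sample_ids),
        "miR", "raw counts",
    )
    samples = SampleTable(stages)

    annotation, same_band_flags = _make_annotation(config, gene_ids, mir_ids, rng)

    de_df = pd.DataFrame(
        [
            {"kind": e.kind, "feature_id": e.feature_id,
             "contrast": e.contrast, "log2fc": e.log2fc}
            for e in config.de_plan
        ],
        columns=["kind", "feature_id", "contrast", "log2fc"],
    )
    coup_df = pd.DataFrame(
        [
            {
                "mir_id": cp.mir_id, "gene_id": cp.gene_id, "sign": cp.sign,
                "rho": cp.rho, "active": "|".join(cp.active_phenotypes),
                "category": cp.category, "stage": cp.stage,
                "same_cytoband": same_band_flags.get((cp.mir_id, cp.gene_id), False),
            }
            for cp in config.coupling_plan
        ],
        columns=["mir_id", "gene_id", "sign", "rho", "active", "category",
                 "stage", "same_cytoband"],
    )
    persistent = _find_persistent_mir(config)
    truth = SyntheticTruth(
        de_effects=de_df, couplings=coup_df, annotation=annotation,
        persistent_mir=persistent,
    )
    return gene_mat, mir_mat, samples, annotation, truth


def _find_persistent_mir(config: SimulationConfig) -> str | None:
    """A miR planted DE in all four contiguous contrasts, if any."""
    labels = {c.label for c in contiguous_contrasts()}
    by_mir: dict[str, set[str]] = {}
    for eff in config.de_plan:
        if eff.kind == "miR":
            by_mir.setdefault(eff.feature_id, set()).add(eff.contrast)
    hits = sorted(m for m, labs in by_mir.items() if labs >= labels)
    return hits[0] if hits else None


def _make_annotation(
    config: SimulationConfig,
    gene_ids: list[str],
    mir_ids: list[str],
    rng: np.random.Generator,
) -> tuple[FeatureAnnotation, dict[tuple[str, str], bool]]:
    plan = config.annotation_plan
    chroms = plan.chromosomes
    bands = plan.bands
    span = plan.band_span

    def draw_locus():
        ci = rng.integers(len(chroms))
        bi = rng.integers(len(bands))
        return ci, bi

    def start_in_band(bi: int) -> int:
        return int(rng.integers(bi * span + 1, (bi + 1) * span - 200_000))

    loci: dict[str, tuple[int, int, int]] = {}  # fid -> (chrom idx, band idx, start)

    # deterministic count of same-cytoband coupled pairs; a feature shared
    # by several couplings keeps its first placement, so the recorded flag
    # is derived from the *realized* loci afterwards
    couplings = list(config.coupling_plan)
    n_same = int(round(plan.same_cytoband_fraction * len(couplings)))
    order = rng.permutation(len(couplings))
    for rank, idx in enumerate(order):
        cp = couplings[idx]
        if rank < n_same:
            # co-place in one band, honoring any earlier placement
            if cp.mir_id in loci:
                ci, bi, _ = loci[cp.mir_id]
            elif cp.gene_id in loci:
                ci, bi, _ = loci[cp.gene_id]
            else:
                ci, bi = draw_locus()
            start_m = start_in_band(bi)
            start_g = min(start_m + int(rng.integers(1_000, 100_000)), (bi + 1) * span - 1_000)
            loci.setdefault(cp.mir_id, (ci, bi, start_m))
            loci.setdefault(cp.gene_id, (ci, bi, start_g))
        else:
            # aim at two *different* chromosomes so the flag is clearly False
            if cp.mir_id in loci:
                ci, bi, _ = loci[cp.mir_id]
            else:
                ci, bi = draw_locus()
                loci[cp.mir_id] = (ci, bi, start_in_band(bi))
            cj = (ci + 1 + int(rng.integers(len(chroms) - 1))) % len(chroms)
            bj = int(rng.integers(len(bands)))
            loci.setdefault(cp.gene_id, (cj, bj, start_in_band(bj)))
    same_flags = {
        (cp.mir_id, cp.gene_id): loci[cp.mir_id][:2] == loci[cp.gene_id][:2]
        for cp in couplings
    }

    rows = []
    unannot = set(config.unannotated_features)
    for fid, kind in [(g, "gene") for g in gene_ids] + [(m, "miRNA") for m in mir_ids]:
        if fid in unannot:
            continue
        if fid in loci:
            ci, bi, start = loci[fid]
        else:
            ci, bi = draw_locus()
            start = start_in_band(bi)
        length = 10_000 if kind == "gene" else 100
        rows.append(
            {
                "feature_id": fid,
                "chromosome": chroms[ci],
                "cytoband": f"{chroms[ci]}{bands[bi]}",
                "start": start,
                "end": start + length,
                "strand": "+" if rng.integers(2) else "-",
                "biotype": "protein_coding" if kind == "gene" else "miRNA",
            }
        )
    table = pd.DataFrame(rows).set_index("feature_id")
    return FeatureAnnotation(table), same_flags


# ---------------------------------------------------------------------------
# The default study
# ---------------------------------------------------------------------------

#: Stage-keyed orientation of planted DE around the persistent miR's sign
#: pattern (under, under, over, under): in a contrast where the persistent
#: miR is *under*, every other planted DE gene is under (so the only
#: over-genes are the persistent miR's targets); in the over contrast the
#: orientation flips.  Both canonical orientations thus occur in the study.
_PERSISTENT_PATTERN = {"I": -1.5, "II": -2.0, "III": 2.0, "IV": -2.0}


def default_study(seed: int = 0) -> SimulationConfig:
    """The canonical desk-scale configuration: 300 genes, 50 miRs, five
    phenotypes with an imbalanced sample plan (stage I largest), NB
    dispersion 0.1, 30 planted couplings (20 negative with DE endpoints
    keyed to stages, 5 tumor-only persistent, 5 positive distractors), one
    persistent miR with stage-varying targets, and 50% same-cytoband
    placement of coupled pairs."""
    contrasts = {c.test: c.label for c in contiguous_contrasts()}
    de_plan: list[DEEffect] = []
    coupling_plan: list[Coupling] = []
    overrides: dict[str, object] = {}
    planted_range = (2.0, 2.8)

    # persistent miR: DE in every contiguous contrast, one coupling per stage
    pm = "miR-10"
    overrides[pm] = (2.6, 2.9)
    pm_targets = {"I": ["G0101", "G0102", "G0103"], "II": ["G0104"],
                  "III": ["G0105"], "IV": ["G0106"]}
    for stage, lfc in _PERSISTENT_PATTERN.items():
        de_plan.append(DEEffect(contrasts[stage], pm, "miR", lfc))
        target_lfc = 2.2 if lfc < 0 else -2.0  # opposite status to the miR
        for gene in pm_targets[stage]:
            de_plan.append(DEEffect(contrasts[stage], gene, "gene", target_lfc))
            overrides[gene] = planted_range
            coupling_plan.append(
                Coupling(pm, gene, -1, 0.8, (stage,), "stage", stage)
            )

    # stage-keyed regular couplings; orientation aligned with the persistent
    # miR's sign in that contrast (see _PERSISTENT_PATTERN note)
    regular = {
        "I": [("miR-01", "G0001"), ("miR-02", "G0002"),
              ("miR-03", "G0003"), ("miR-04", "G0004")],
        "II": [("miR-05", "G0005"), ("miR-06", "G0006"),
               ("miR-07", "G0007"), ("miR-08", "G0008")],
        "III": [("miR-11", "G0009"), ("miR-12", "G0010"), ("miR-13", "G0011")],
        "IV": [("miR-14", "G0012"), ("miR-15", "G0013"), ("miR-16", "G0014")],
    }
    for stage, pairs in regular.items():
        pm_under = _PERSISTENT_PATTERN[stage] < 0
        mir_lfc, gene_lfc = (1.2, -2.2) if pm_under else (-1.2, 2.2)
        for mir, gene in pairs:
            de_plan.append(DEEffect(contrasts[stage], mir, "miR", mir_lfc))
            de_plan.append(DEEffect(contrasts[stage], gene, "gene", gene_lfc))
            overrides[mir] = planted_range
            overrides[gene] = planted_range
            coupling_plan.append(Coupling(mir, gene, -1, 0.8, (stage,), "stage", stage))

    # five tumor-only persistent couplings (no DE; present I-IV, absent NT)
    for i, (mir, gene) in enumerate(
        [("miR-21", "G0201"), ("miR-22", "G0202"), ("miR-23", "G0203"),
         ("miR-24", "G0204"), ("miR-25", "G0205")]
    ):
        coupling_plan.append(
            Coupling(mir, gene, -1, 0.8, ("I", "II", "III", "IV"), "tumor_only")
        )

    # five positive-sign distractors, active everywhere (removed by the
    # opposite-sign filter, present in every top-K network)
    for mir, gene in [("miR-31", "G0211"), ("miR-32", "G0212"), ("miR-33", "G0213"),
                      ("miR-34", "G0214"), ("miR-35", "G0215")]:
        coupling_plan.append(Coupling(mir, gene, 1, 0.8, STAGE_ORDER, "positive"))

    # uncoupled DE features per contrast (realistic background DE); gene
    # orientation matches the persistent miR's sign, miRs go both ways
    extra_genes = {"I": ["G0121", "G0122", "G0123"], "II": ["G0124", "G0125", "G0126"],
                   "III": ["G0127", "G0128", "G0129"], "IV": ["G0130", "G0131", "G0132"]}
    extra_mirs = {"I": ["miR-41", "miR-42"], "II": ["miR-43", "miR-44"],
                  "III": ["miR-45", "miR-46"], "IV": ["miR-47", "miR-48"]}
    for stage in ("I", "II", "III", "IV"):
        pm_under = _PERSISTENT_PATTERN[stage] < 0
        gene_lfc = -2.0 if pm_under else 2.0
        for gene in extra_genes[stage]:
            de_plan.append(DEEffect(contrasts[stage], gene, "gene", gene_lfc))
            overrides[gene] = planted_range
        for j, mir in enumerate(extra_mirs[stage]):
            de_plan.append(DEEffect(contrasts[stage], mir, "miR", 1.0 if j % 2 == 0 else -1.0))
            overrides[mir] = planted_range

    # filter-exercising fillers: high-zero, unannotated, low-mean genes
    for fid in ("G0287", "G0288"):
        overrides[fid] = 0.2  # mean ~1.6
    for fid in [f"G{i:04d}" for i in range(291, 301)]:
        overrides[fid] = 0.3  # mean ~2, removed by the mean filter
    dispersion_overrides = {"G0287": 8.0, "G0288": 8.0}

    return SimulationConfig(
        n_genes=300,
        n_mirs=50,
        samples_per_phenotype={"NT": 40, "I": 60, "II": 40, "III": 40, "IV": 40},
        baseline_log10_range=(1.5, 3.0),
        dispersion=0.1,
        dispersion_overrides=dispersion_overrides,
        baseline_log10_overrides=overrides,
        library_size_cv=0.25,
        de_plan=de_plan,
        coupling_plan=coupling_plan,
        annotation_plan=AnnotationPlan(same_cytoband_fraction=0.5),
        unannotated_features=("G0289", "G0290"),
        seed=seed,
    )


#: Top-K retention at the default synthetic scale: the same retention
#: fraction as the study design (100,000 of 275 x 16,227 = 2.24%) applied
#: to 50 x 300 = 15,000 candidate pairs.
DEFAULT_STUDY_K = 336


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
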