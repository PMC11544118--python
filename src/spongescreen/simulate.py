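"""Synthetic data with planted ceRNA structure, for end-to-end recovery tests.

The generator emits everything the screening pipeline consumes:

* an RNA-seq count matrix (lncRNA / miRNA / mRNA genes x tumor+normal
  samples) in which each planted sponge triplet shares a latent Gaussian
  factor — the miRNA loads negatively, the lncRNA and mRNA positively —
  before a negative-binomial quantile transform, so the requested Spearman
  correlations survive the count scale;
* two interaction tables per edge class (lncRNA->miRNA and miRNA->mRNA)
  containing every planted edge plus uniformly random decoys;
* a clinical table whose survival times are exponential with log-hazard
  proportional to the z-scored hub-lncRNA expression;
* a 22-cell-type immune fraction table in which one cell type's abundance
  is rank-coupled to the hub;
* a qPCR Ct plate for the paired tumor/adjacent validation arithmetic.

A :class:`SimTruth` record carries the planted triplets, differential
genes, true hazard coefficient and coupled cell type so tests can score
recovery.  Everything is driven by one integer seed and is byte-stable.

Triplet layout: the first two planted triplets share the hub lncRNA and
hub miRNA and terminate at the two designated ligand mRNAs (a PD-L1-like
and a PD-L2-like endpoint), mirroring a lncRNA that dually regulates two
immune-checkpoint ligands through one sponged miRNA; the remaining
triplets are disjoint sponge units acting as positive controls.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .matrix import ExpressionMatrix

# The 22 leukocyte labels of the standard LM22 signature; the fraction
# table mimics a deconvolution output over these types.
LM22_CELL_TYPES = [
    "B cells naive", "B cells memory", "Plasma cells",
    "T cells CD8", "T cells CD4 naive", "T cells CD4 memory resting",
    "T cells CD4 memory activated", "T cells follicular helper",
    "T cells regulatory (Tregs)", "T cells gamma delta",
    "NK cells resting", "NK cells activated",
    "Monocytes", "Macrophages M0", "Macrophages M1", "Macrophages M2",
    "Dendritic cells resting", "Dendritic cells activated",
    "Mast cells resting", "Mast cells activated",
    "Eosinophils", "Neutrophils",
]

COUPLED_CELL_TYPE = "Macrophages M2"


def spearman_to_gaussian_rho(s: float) -> float:
    """Gaussian-copula correlation that yields Spearman ``s`` (Pearson's
    classic bivariate-normal identity rho_S = (6/pi) asin(rho/2), inverted)."""
    return 2.0 * math.sin(math.pi * s / 6.0)


@dataclass
class SimConfig:
    """Study conditions for the synthetic bundle.

    Defaults encode the scale at which the screen is exercised: 200 tumor
    vs 50 normal samples, 10 planted triplets at sponge Spearman 0.8 among
    500 decoy edges per interaction table, hub log2 fold change 2, true
    Cox log-hazard ln(1.74) per SD of hub expression, 30% censoring and an
    M2-macrophage coupling of 0.47.
    """

    n_tumor: int = 200
    n_normal: int = 50
    n_lnc: int = 500
    n_mi: int = 100
    n_mrna: int = 300
    n_triplets: int = 10
    sponge_strength: float = 0.8
    de_lfc: float = 2.0
    nb_dispersion: float = 0.15
    libsize_range: tuple = (500_000.0, 2_000_000.0)
    beta_hazard: float = math.log(1.74)
    censor_rate: float = 0.3
    fp_edges: int = 500
    frac_coupling: float = 0.47
    stage_coupling: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal", "n_lnc", "n_mi", "n_mrna", "n_triplets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.sponge_strength < 1.0):
            raise ValueError("sponge_strength must lie in (0, 1)")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must lie in [0, 1)")
        if not (-1.0 < self.frac_coupling < 1.0):
            raise ValueError("frac_coupling must lie in (-1, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ValueError("libsize_range must satisfy 0 < lo <= hi")
        if self.fp_edges < 0:
            raise ValueError("fp_edges must be non-negative")
        if self.n_triplets > min(self.n_lnc, self.n_mi, self.n_mrna):
            raise ValueError(
                "n_triplets may not exceed min(n_lnc, n_mi, n_mrna)")


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the synthetic bundle."""

    planted_triplets: list  # (lnc_id, mi_id, mrna_id)
    de_genes: list          # (gene_id, true signed log2FC)
    beta_hazard: float
    coupled_celltype: str
    hub_lnc: str
    hub_mi: str
    ligands: tuple          # the two ligand mRNA endpoints of the hub

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_triplets"] = [list(t) for t in self.planted_triplets]
        d["de_genes"] = [[g, float(l)] for g, l in self.de_genes]
        d["ligands"] = list(self.ligands)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            planted_triplets=[tuple(t) for t in d["planted_triplets"]],
            de_genes=[(g, float(l)) for g, l in d["de_genes"]],
            beta_hazard=float(d["beta_hazard"]),
            coupled_celltype=d["coupled_celltype"],
            hub_lnc=d["hub_lnc"],
            hub_mi=d["hub_mi"],
            ligands=tuple(d["ligands"]),
        )


def _gene_ids(config: SimConfig):
    lnc = [f"LNC{i:04d}" for i in range(1, config.n_lnc + 1)]
    mi = [f"MIR{i:04d}" for i in range(1, config.n_mi + 1)]
    mrna = [f"MR{i:04d}" for i in range(1, config.n_mrna + 1)]
    return lnc, mi, mrna


def _planted_layout(config: SimConfig):
    """Triplet list plus per-unit gene membership with loading signs."""
    lnc, mi, mrna = _gene_ids(config)
    triplets: list[tuple[str, str, str]] = []
    units: list[list[tuple[str, float]]] = []  # (gene, sign) per latent unit
    if config.n_triplets >= 2:
        ligands = (mrna[0], mrna[1])
        triplets.append((lnc[0], mi[0], ligands[0]))
        triplets.append((lnc[0], mi[0], ligands[1]))
        units.append([(lnc[0], +1.0), (mi[0], -1.0),
                      (ligands[0], +1.0), (ligands[1], +1.0)])
        for k in range(2, config.n_triplets):
            t = (lnc[k - 1], mi[k - 1], mrna[k])
            triplets.append(t)
            units.append([(t[0], +1.0), (t[1], -1.0), (t[2], +1.0)])
    else:
        ligands = (mrna[0],)
        triplets.append((lnc[0], mi[0], mrna[0]))
        units.append([(lnc[0], +1.0), (mi[0], -1.0), (mrna[0], +1.0)])
    return triplets, units, ligands


def _nb_ppf(q: np.ndarray, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Quantile of NB(mean, var = mean + dispersion*mean^2); Poisson at 0."""
    if dispersion <= 0:
        return sps.poisson.ppf(q, mu=mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return sps.nbinom.ppf(q, size, p)


def simulate_expression(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Generate the count matrix and its ground-truth record.

    Planted genes within a sponge unit draw from a shared latent Gaussian
    (loading sqrt(rho), sign per role) and pass through a per-gene NB
    quantile transform; the transform is monotone, so the Gaussian-copula
    calibration carries the requested Spearman onto the counts.  Planted
    lncRNAs and mRNAs carry +de_lfc in tumor samples and planted miRNAs
    -de_lfc; all other genes are independent NB noise.
    """
    rng = np.random.default_rng([0, config.seed])
    lnc, mi, mrna = _gene_ids(config)
    genes = lnc + mi + mrna
    n_genes = len(genes)
    n_samples = config.n_tumor + config.n_normal
    samples = ([f"TUM{i:04d}" for i in range(1, config.n_tumor + 1)]
               + [f"NRM{i:04d}" for i in range(1, config.n_normal + 1)])
    is_tumor = np.array([1] * config.n_tumor + [0] * config.n_normal)

    triplets, units, ligands = _planted_layout(config)
    planted_genes = sorted({g for unit in units for g, _ in unit})

    # Per-gene baseline CPM: null genes span a broad log-uniform range so
    # the planted genes hold only a small share of the library mass —
    # otherwise their tumor up-shift inflates the library size and the
    # CPM composition artifact attenuates every estimated fold change.
    # Planted genes are kept well-expressed so the count transform does
    # not drown the planted rank correlation in ties.
    base_cpm = np.exp(rng.uniform(np.log(10.0), np.log(5000.0), size=n_genes))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in planted_genes:
        base_cpm[gene_pos[g]] = np.exp(rng.uniform(np.log(100.0), np.log(500.0)))

    # signed planted log2 fold changes (tumor minus normal)
    lfc = np.zeros(n_genes)
    de_genes: list[tuple[str, float]] = []
    for t in triplets:
        for g, s in ((t[0], +1.0), (t[1], -1.0), (t[2], +1.0)):
            if lfc[gene_pos[g]] == 0.0:
                lfc[gene_pos[g]] = s * config.de_lfc
                de_genes.append((g, s * config.de_lfc))

    lo, hi = config.libsize_range
    libsize = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))

    rho = spearman_to_gaussian_rho(config.sponge_strength)
    a = math.sqrt(rho)
    b = math.sqrt(1.0 - rho)

    # latent Gaussian field: independent by default, shared factor per unit
    z = rng.standard_normal((n_genes, n_samples))
    for unit in units:
        factor = rng.standard_normal(n_samples)
        for g, sign in unit:
            z[gene_pos[g]] = sign * a * factor + b * rng.standard_normal(n_samples)

    mean = (base_cpm[:, None]
            * np.power(2.0, lfc[:, None] * is_tumor[None, :])
            * libsize[None, :] / 1e6)

    counts = np.empty((n_genes, n_samples))
    planted_idx = np.array([gene_pos[g] for g in planted_genes])
    planted_mask = np.zeros(n_genes, dtype=bool)
    planted_mask[planted_idx] = True
    # planted rows: copula quantile transform (rank-preserving)
    q = sps.norm.cdf(z[planted_mask])
    counts[planted_mask] = _nb_ppf(q, mean[planted_mask], config.nb_dispersion)
    # null rows: direct NB sampling (distributionally identical, cheaper)
    m_null = mean[~planted_mask]
    if config.nb_dispersion > 0:
        size = 1.0 / config.nb_dispersion
        p = size / (size + m_null)
        counts[~planted_mask] = rng.negative_binomial(size, p)
    else:
        counts[~planted_mask] = rng.poisson(m_null)

    values = pd.DataFrame(counts, index=genes, columns=samples)
    condition = pd.Series(np.where(is_tumor == 1, "tumor", "normal"),
                          index=samples)
    expr = ExpressionMatrix(values=values, condition=condition, scale="counts")
    truth = SimTruth(
        planted_triplets=triplets,
        de_genes=de_genes,
        beta_hazard=config.beta_hazard,
        coupled_celltype=COUPLED_CELL_TYPE,
        hub_lnc=triplets[0][0],
        hub_mi=triplets[0][1],
        ligands=ligands,
    )
    return expr, truth


# ---------------------------------------------------------------------------
# interaction tables


def simulate_interaction_tables(truth: SimTruth, config: SimConfig) -> dict:
    """Two prediction sources per edge class, planted edges in both.

    Returns ``{"lnc_mi": [table, table], "mi_mrna": [table, table]}`` where
    each table is a DataFrame (regulator_id, target_id, source_db).  Decoy
    edges are drawn uniformly without replacement from the full id
    universe, independently per source, so only a birthday-collision
    handful of decoys survives a source intersection.
    """
    from .cerna import InteractionTable  # deferred: avoids import cycle

    lnc, mi, mrna = _gene_ids(config)
    planted_lnc_mi = sorted({(t[0], t[1]) for t in truth.planted_triplets})
    planted_mi_mrna = sorted({(t[1], t[2]) for t in truth.planted_triplets})

    def one_table(regulators, targets, planted, source_db, edge_class, sub):
        local = np.random.default_rng([2, config.seed, sub])
        universe = len(regulators) * len(targets)
        planted_flat = {regulators.index(r) * len(targets) + targets.index(t)
                        for r, t in planted}
        n_fp = min(config.fp_edges, universe - len(planted_flat))
        decoys: set[int] = set()
        while len(decoys) < n_fp:
            draw = local.integers(0, universe, size=n_fp - len(decoys))
            decoys.update(int(d) for d in draw if d not in planted_flat)
        edges = set(planted)
        for d in sorted(decoys):
            edges.add((regulators[d // len(targets)], targets[d % len(targets)]))
        return InteractionTable(edges=edges, edge_class=edge_class,
                                source_db=source_db)

    return {
        "lnc_mi": [
            one_table(lnc, mi, planted_lnc_mi, "mircode_sim", "lnc_mi", 0),
            one_table(lnc, mi, planted_lnc_mi, "rnahybrid_sim", "lnc_mi", 1),
        ],
        "mi_mrna": [
            one_table(mi, mrna, planted_mi_mrna, "targetscan_sim", "mi_mrna", 2),
            one_table(mi, mrna, planted_mi_mrna, "mirdb_sim", "mi_mrna", 3),
        ],
    }


# ---------------------------------------------------------------------------
# clinical / survival


def hub_expression_z(expr: ExpressionMatrix, hub_lnc: str) -> pd.Series:
    """z-scored log2(CPM+1) of the hub lncRNA over tumor samples."""
    from .diffexpr import cpm_log_normalize

    tumor = expr.tumor_only()
    log_expr = cpm_log_normalize(tumor) if tumor.scale == "counts" else tumor
    x = log_expr.expression_of(hub_lnc).astype(float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("hub expression is constant; cannot z-score")
    return (x - x.mean()) / sd


def simulate_clinical(expr: ExpressionMatrix, truth: SimTruth,
                      config: SimConfig) -> pd.DataFrame:
    """Clinical table for the tumor samples.

    Survival times are exponential with rate lambda0*exp(beta*z) where z is
    the z-scored hub expression; censoring is an independent exponential
    whose rate is solved (bisection on the expected censored fraction
    c/(c+lambda_i) averaged over patients) to hit ``censor_rate``.  Ordinal
    stage is drawn from a cumulative-logit model shifted by the hub
    expression tertile; the remaining covariates are uncoupled.
    """
    rng = np.random.default_rng([3, config.seed])
    z = hub_expression_z(expr, truth.hub_lnc)
    n = len(z)
    lam0 = math.log(2.0) / 730.0  # two-year median survival at z = 0
    lam = lam0 * np.exp(config.beta_hazard * z.values)
    t_event = rng.exponential(1.0 / lam)
    if config.censor_rate > 0:
        def censored_frac(c):
            return float(np.mean(c / (c + lam))) - config.censor_rate
        c_rate = optimize.brentq(censored_frac, 1e-12, 1e6)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1.0 / 24.0)  # avoid zero follow-up

    # stage shifted by hub tertile through cumulative logits
    tert = pd.qcut(z.rank(method="first"), 3, labels=False).values
    base_cum = np.array([0.20, 0.55, 0.85])  # P(stage <= I, II, III)
    theta = np.log(base_cum / (1 - base_cum))
    cum = 1.0 / (1.0 + np.exp(-(theta[None, :]
                                - config.stage_coupling * tert[:, None])))
    u = rng.uniform(size=n)
    stage_idx = (u[:, None] > cum).sum(axis=1)  # 0..3
    stages = np.array(["I", "II", "III", "IV"])[stage_idx]

    table = pd.DataFrame({
        "time": time,
        "event": event,
        "age": np.clip(rng.normal(65, 10, size=n), 30, 90).round(1),
        "sex": rng.choice(["male", "female"], size=n),
        "stage": stages,
        "grade": rng.choice(["G1", "G2", "G3"], size=n, p=[0.1, 0.4, 0.5]),
        "t_stage": rng.choice(["T1", "T2", "T3", "T4"], size=n,
                              p=[0.05, 0.2, 0.45, 0.3]),
        "n_stage": rng.choice(["N0", "N1", "N2", "N3"], size=n,
                              p=[0.3, 0.27, 0.2, 0.23]),
        "m_stage": rng.choice(["M0", "M1"], size=n, p=[0.9, 0.1]),
        "msi": rng.binomial(1, 0.20, size=n),
        "ebv": rng.binomial(1, 0.09, size=n),
    }, index=z.index)
    table.index.name = "sample_id"
    return table


# ---------------------------------------------------------------------------
# immune fractions


def simulate_fractions(expr: ExpressionMatrix, truth: SimTruth,
                       config: SimConfig) -> pd.DataFrame:
    """22-cell-type fraction table (cell types x tumor samples).

    The coupled type's fraction is a Beta marginal joined to the hub
    expression through a Gaussian copula at the correlation that yields
    Spearman ``frac_coupling``; the other 21 types share the remaining
    mass via a Dirichlet draw, so every column sums to one exactly.
    """
    rng = np.random.default_rng([4, config.seed])
    z = hub_expression_z(expr, truth.hub_lnc)
    n = len(z)
    r = spearman_to_gaussian_rho(config.frac_coupling)
    w = r * z.values + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    f_coupled = sps.beta.ppf(sps.norm.cdf(w), a=2.0, b=20.0)

    others = [c for c in LM22_CELL_TYPES if c != truth.coupled_celltype]
    alpha = np.linspace(0.5, 4.0, len(others))
    rest = rng.dirichlet(alpha, size=n)  # n x 21, rows sum to 1
    out = pd.DataFrame(index=LM22_CELL_TYPES, columns=z.index, dtype=float)
    out.loc[truth.coupled_celltype] = f_coupled
    out.loc[others] = (rest * (1.0 - f_coupled)[:, None]).T
    out.index.name = "cell_type"
    return out


# ---------------------------------------------------------------------------
# qPCR plate


def simulate_ct_table(config: SimConfig, n_pairs: int = 23,
                      target_gene: str = "HUB_LNC",
                      reference_gene: str = "ACTB",
                      tumor_shift_cycles: float = -1.5,
                      ct_sd: float = 0.25,
                      n_replicates: int = 3) -> pd.DataFrame:
    """Triplicate Ct plate for paired tumor/adjacent validation.

    Tumor wells of the target gene sit ``tumor_shift_cycles`` below the
    adjacent-tissue wells (fewer cycles = more transcript); the reference
    gene is flat.  Long format: sample_id, gene, condition, replicate, ct.
    """
    rng = np.random.default_rng([5, config.seed])
    rows = []
    for i in range(1, n_pairs + 1):
        base_target = rng.normal(26.0, 1.0)
        base_ref = rng.normal(18.0, 0.5)
        for condition, shift in (("tumor", tumor_shift_cycles), ("adjacent", 0.0)):
            sid = f"P{i:02d}_{condition}"
            for rep in range(1, n_replicates + 1):
                rows.append((sid, target_gene, condition, rep,
                             base_target + shift + rng.normal(0, ct_sd)))
                rows.append((sid, reference_gene, condition, rep,
                             base_ref + rng.normal(0, ct_sd)))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "condition",
                                       "replicate", "ct"])
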