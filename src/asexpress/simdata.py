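"""Synthetic orthologue count matrices and pooled allele depths.

The generator emulates the sampling design of a multi-lineage brine-shrimp
expression study: three sexual species (males + females) and three asexual
female-only lineages related by a fixed topology in which the asexual
lineages and their closest sexual relative are separated by near-zero
branches. Log2 expression evolves by Brownian motion along the tree with a
class-specific rate. A per-gene sex effect of magnitude delta is centered
on the base level (female-biased: F = base + delta/2, M = base - delta/2;
male-biased mirrored), so losing the bias through turnover moves BOTH
sexes back toward the unbiased level — the mechanism behind apparent
masculinization of females (ancestrally female-high genes fall, female-low
ones rise) with its mirror-image feminization in males. The sex-effect
state undergoes turnover along branches; asexual female expression can be shifted
toward the male expression state (masculinization); a shared "core
asexuality" gene set plus per-lineage private sets carry sexual-vs-asexual
DE effects; counts are negative binomial (Var = mu + alpha mu^2) with
log-normal library size factors.

All generators are deterministic given ``config.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLASSES = ("UBG", "FBG", "MBG")  # integer codes 0, 1, 2

# Default topology: outgroup sexual species, a second sexual species, then a
# near-zero-branch clade of the third sexual species and the asexuals.
DEFAULT_TOPOLOGY: dict[str, tuple[str | None, float]] = {
    "root": (None, 0.0),
    "sinica": ("root", 0.5),
    "nodeA": ("root", 0.25),
    "urmiana": ("nodeA", 0.25),
    "nodeB": ("nodeA", 0.24),
    "kazakhstan": ("nodeB", 0.01),
    "asex1": ("nodeB", 0.01),
    "asex2": ("nodeB", 0.01),
    "asex3": ("nodeB", 0.01),
}
SEXUAL_LINEAGES = ("sinica", "urmiana", "kazakhstan")
ASEXUAL_LINEAGES = ("asex1", "asex2", "asex3")

DEFAULT_LINEAGE_F = {
    "sinica": 0.3,
    "urmiana": 0.15,
    "kazakhstan": 0.01,
    "asex1": 0.01,
    "asex2": 0.01,
    "asex3": 0.01,
}


@dataclass
class SimulationConfig:
    """Parameters of the generative model. Defaults define the study
    conditions the analyses are validated against."""

    n_genes: int = 6000
    tissues: tuple[str, ...] = ("head", "gonad")
    n_replicates: int = 2
    frac_fbg: float = 0.15
    frac_mbg: float = 0.15
    sexbias_lfc_mean: float = 2.0
    sexbias_lfc_sd: float = 0.5
    sexbias_lfc_min: float = 1.0
    sigma2_per_class: dict = field(
        default_factory=lambda: {"FBG": 0.2, "MBG": 0.2, "UBG": 0.2}
    )
    turnover_tau: float = 0.0
    masculinization_m: float = 0.0
    n_core_asex_genes: int = 30
    core_lfc: float = 3.0
    n_private_asex_genes: int = 20
    private_lfc: float = 3.0
    dispersion: float = 0.05
    libsize_lognormal_sd: float = 0.3
    base_log2_mean: float = 6.0
    base_log2_sd: float = 1.5
    length_log_mean: float = 7.3  # natural-log bp; median ~1480 bp
    length_log_sd: float = 0.45
    topology: dict = field(default_factory=lambda: dict(DEFAULT_TOPOLOGY))
    sexual_lineages: tuple[str, ...] = SEXUAL_LINEAGES
    asexual_lineages: tuple[str, ...] = ASEXUAL_LINEAGES
    # allele-depth simulation
    n_sites: int = 5000
    depth_mean: float = 50.0
    lineage_f: dict = field(default_factory=lambda: dict(DEFAULT_LINEAGE_F))
    qual_mean: float = 50.0
    qual_sd: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_fbg", "frac_mbg", "turnover_tau", "masculinization_m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_fbg + self.frac_mbg > 1.0:
            raise ValueError("frac_fbg + frac_mbg > 1")
        if not isinstance(self.n_replicates, (int, np.integer)) or self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth_mean <= 0:
            raise ValueError("depth distribution must have positive support")
        for lin in self.sexual_lineages + self.asexual_lineages:
            if lin not in self.topology:
                raise ValueError(f"lineage {lin!r} not in topology")


@dataclass
class SimulationTruth:
    """Ground truth against which recovery is scored."""

    class_root: np.ndarray  # integer codes per gene at the root
    class_per_lineage: dict  # lineage -> integer codes per gene at the tip
    core_genes: dict  # gene_id -> +1/-1 direction
    private_genes: dict  # lineage -> {gene_id: direction}
    mean_log2: dict  # (lineage, tissue, sex) -> per-gene mean log2 expression
    size_factors: pd.Series | None = None

    def class_labels(self, lineage: str, gene_ids) -> pd.Series:
        codes = self.class_per_lineage[lineage]
        return pd.Series([CLASSES[c] for c in codes], index=gene_ids)


def _preorder(topology: dict) -> list[str]:
    children: dict[str, list[str]] = {}
    root = None
    for node, (parent, _) in topology.items():
        if parent is None:
            root = node
        else:
            children.setdefault(parent, []).append(node)
    if root is None:
        raise ValueError("topology has no root")
    order, stack = [], [root]
    while stack:
        node = stack.pop(0)
        order.append(node)
        stack = children.get(node, []) + stack
    return order


def _evolve_states(cfg: SimulationConfig, rng: np.random.Generator):
    """Brownian evolution of base log2 expression plus turnover of the
    per-gene sex-effect state along the topology."""
    g, t = cfg.n_genes, len(cfg.tissues)
    class_root = rng.choice(
        [1, 2, 0], size=g, p=[cfg.frac_fbg, cfg.frac_mbg, 1 - cfg.frac_fbg - cfg.frac_mbg]
    )
    sigma2 = np.array([cfg.sigma2_per_class[CLASSES[c]] for c in class_root])

    def draw_delta(n):
        return np.clip(
            rng.normal(cfg.sexbias_lfc_mean, cfg.sexbias_lfc_sd, size=n),
            cfg.sexbias_lfc_min,
            None,
        )

    base_root = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=(g, t))
    delta_root = np.where(class_root != 0, draw_delta(g), 0.0)

    node_class = {}
    node_delta = {}
    node_base = {}
    order = _preorder(cfg.topology)
    root = order[0]
    node_class[root] = class_root.copy()
    node_delta[root] = delta_root.copy()
    node_base[root] = base_root
    for node in order[1:]:
        parent, length = cfg.topology[node]
        step = rng.normal(0.0, 1.0, size=(g, t)) * np.sqrt(sigma2 * length)[:, None]
        node_base[node] = node_base[parent] + step
        cls = node_class[parent].copy()
        dlt = node_delta[parent].copy()
        if cfg.turnover_tau > 0 and length > 0:
            p_turn = 1.0 - (1.0 - cfg.turnover_tau) ** length
            biased = cls != 0
            turned = biased & (rng.random(g) < p_turn)
            if turned.any():
                erase = rng.random(g) < 0.5
                redraw = turned & ~erase
                cls[turned & erase] = 0
                dlt[turned & erase] = 0.0
                if redraw.any():
                    new_sex = rng.choice([1, 2], size=g)
                    new_delta = draw_delta(g)
                    cls[redraw] = new_sex[redraw]
                    dlt[redraw] = new_delta[redraw]
        node_class[node] = cls
        node_delta[node] = dlt
    return class_root, node_class, node_delta, node_base


def simulate_dataset(cfg: SimulationConfig):
    """Generate (counts, sample_meta, gene_meta, truth).

    Counts: genes x samples integer DataFrame. Sexual lineages get M and F
    samples; asexual lineages F only.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    g = cfg.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(g)], name="gene_id")

    lengths = np.rint(
        np.exp(rng.normal(cfg.length_log_mean, cfg.length_log_sd, size=g))
    ).astype(int)
    lengths = np.clip(lengths, 200, 20000)

    class_root, node_class, node_delta, node_base = _evolve_states(cfg, rng)
    tip_lineages = list(cfg.sexual_lineages) + list(cfg.asexual_lineages)

    # tip mean log2 expression per sex
    mean_log2: dict[tuple[str, str, str], np.ndarray] = {}
    for lin in tip_lineages:
        base = node_base[lin]
        cls = node_class[lin]
        dlt = node_delta[lin]
        f_add = np.where(cls == 1, dlt / 2.0, np.where(cls == 2, -dlt / 2.0, 0.0))
        m_add = np.where(cls == 2, dlt / 2.0, np.where(cls == 1, -dlt / 2.0, 0.0))
        for ti, tissue in enumerate(cfg.tissues):
            mean_log2[(lin, tissue, "F")] = base[:, ti] + f_add
            mean_log2[(lin, tissue, "M")] = base[:, ti] + m_add

    # masculinization of asexual female means
    m = cfg.masculinization_m
    if m > 0:
        for lin in cfg.asexual_lineages:
            for tissue in cfg.tissues:
                xf = mean_log2[(lin, tissue, "F")]
                xm = mean_log2[(lin, tissue, "M")]
                mean_log2[(lin, tissue, "F")] = (1.0 - m) * xf + m * xm

    # core and private asexuality genes, drawn among root-unbiased genes
    n_asex = len(cfg.asexual_lineages)
    n_special = cfg.n_core_asex_genes + n_asex * cfg.n_private_asex_genes
    ubg_pool = np.flatnonzero(class_root == 0)
    if n_special > len(ubg_pool):
        raise ValueError("not enough unbiased genes for core/private sets")
    special = rng.choice(ubg_pool, size=n_special, replace=False)
    core_idx = special[: cfg.n_core_asex_genes]
    core_sign = rng.choice([1.0, -1.0], size=len(core_idx))
    core_genes = {gene_ids[i]: int(s) for i, s in zip(core_idx, core_sign)}
    private_genes: dict[str, dict] = {}
    off = cfg.n_core_asex_genes
    for lin in cfg.asexual_lineages:
        idx = special[off : off + cfg.n_private_asex_genes]
        sign = rng.choice([1.0, -1.0], size=len(idx))
        private_genes[lin] = {gene_ids[i]: int(s) for i, s in zip(idx, sign)}
        off += cfg.n_private_asex_genes
    for lin in cfg.asexual_lineages:
        for tissue in cfg.tissues:
            x = mean_log2[(lin, tissue, "F")].copy()
            x[core_idx] += core_sign * cfg.core_lfc
            pidx = np.array([gene_ids.get_loc(k) for k in private_genes[lin]], dtype=int)
            if len(pidx):
                psign = np.array(list(private_genes[lin].values()), dtype=float)
                x[pidx] += psign * cfg.private_lfc
            mean_log2[(lin, tissue, "F")] = x

    # samples and NB counts
    sample_rows = []
    count_cols = {}
    sf_draws = {}
    for lin in tip_lineages:
        sexual = lin in cfg.sexual_lineages
        sexes = ("M", "F") if sexual else ("F",)
        for tissue in cfg.tissues:
            for sex in sexes:
                for rep in range(1, cfg.n_replicates + 1):
                    sid = f"{lin}_{tissue}_{sex}{rep}"
                    sf = float(np.exp(rng.normal(0.0, cfg.libsize_lognormal_sd)))
                    mu = np.exp2(mean_log2[(lin, tissue, sex)]) * sf
                    count_cols[sid] = _nb_draw(rng, mu, cfg.dispersion)
                    sf_draws[sid] = sf
                    sample_rows.append(
                        {
                            "sample_id": sid,
                            "lineage": lin,
                            "sex": sex,
                            "tissue": tissue,
                            "replicate": rep,
                            "mode": "sexual" if sexual else "asexual",
                        }
                    )
    counts = pd.DataFrame(count_cols, index=gene_ids)
    meta = pd.DataFrame(sample_rows).set_index("sample_id")
    gene_meta = pd.DataFrame(
        {
            "length_bp": lengths,
            "true_class": [CLASSES[c] for c in class_root],
        },
        index=gene_ids,
    )
    truth = SimulationTruth(
        class_root=class_root,
        class_per_lineage={lin: node_class[lin] for lin in tip_lineages},
        core_genes=core_genes,
        private_genes=private_genes,
        mean_log2=mean_log2,
        size_factors=pd.Series(sf_draws),
    )
    return counts, meta, gene_meta, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws with Var = mu + alpha mu^2; Poisson limit at alpha = 0."""
    if alpha == 0.0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_null_dataset(
    cfg: SimulationConfig, n_per_group: int = 3
) -> pd.DataFrame:
    """Two groups with identical NB parameters per gene: no true effects.

    Columns A1..An then B1..Bn. Type-I error harness for the DE test.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    g = cfg.n_genes
    mu = np.exp2(rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=g))
    cols = {}
    for grp in ("A", "B"):
        for i in range(1, n_per_group + 1):
            sf = float(np.exp(rng.normal(0.0, cfg.libsize_lognormal_sd)))
            cols[f"{grp}{i}"] = _nb_draw(rng, mu * sf, cfg.dispersion)
    gene_ids = pd.Index([f"g{i:05d}" for i in range(g)], name="gene_id")
    return pd.DataFrame(cols, index=gene_ids)


def simulate_allele_counts(cfg: SimulationConfig):
    """Pooled ref/alt read depths per site x lineage with Balding-Nichols
    style population differentiation.

    Per site: ancestral frequency p0 ~ U(0.15, 0.85); each lineage draws
    its frequency from Beta with mean p0 and differentiation F (lineage_f);
    read depth ~ Poisson(depth_mean); ref reads ~ Binomial(depth, p).
    Returns (table, truth) where truth holds true per-site frequencies and
    per-pair nominal F values.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    lineages = list(cfg.lineage_f)
    n = cfg.n_sites
    p0 = rng.uniform(0.15, 0.85, size=n)
    qual = np.round(rng.normal(cfg.qual_mean, cfg.qual_sd, size=n), 2)  # site property
    rows = []
    true_freqs = {}
    for lin in lineages:
        f = float(cfg.lineage_f[lin])
        if f < 0 or f >= 1:
            raise ValueError(f"lineage F for {lin!r} outside [0, 1)")
        if f == 0.0:
            p = p0.copy()
        else:
            a = p0 * (1.0 - f) / f
            b = (1.0 - p0) * (1.0 - f) / f
            p = rng.beta(a, b)
        true_freqs[lin] = p
        depth = rng.poisson(cfg.depth_mean, size=n)
        depth = np.maximum(depth, 1)
        ref = rng.binomial(depth, p)
        for i in range(n):
            rows.append(
                {
                    "site": f"contig{i // 100}:{(i % 100) + 1}",
                    "lineage": lin,
                    "ref_reads": int(ref[i]),
                    "alt_reads": int(depth[i] - ref[i]),
                    "qual": float(qual[i]),
                    "n_alleles": 2,
                }
            )
    table = pd.DataFrame(rows)
    site_ids = [f"contig{i // 100}:{(i % 100) + 1}" for i in range(n)]
    truth = {
        "true_freqs": pd.DataFrame(true_freqs, index=site_ids),
        "pair_f": {
            (a, b): (cfg.lineage_f[a] + cfg.lineage_f[b]) / 2.0
            for ai, a in enumerate(lineages)
            for b in lineages[ai + 1 :]
        },
        "ancestral_freq": pd.Series(p0, index=site_ids),
    }
    return table, truth


# ---------------------------------------------------------------------------
# on-disk formats


def write_dataset(outdir, counts, meta, gene_meta, truth) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts.to_csv(out / "counts.tsv", sep="\t")
    meta.to_csv(out / "sample_meta.tsv", sep="\t")
    gene_meta.to_csv(out / "gene_meta.tsv", sep="\t")
    payload = {
        "core_genes": truth.core_genes,
        "private_genes": truth.private_genes,
        "class_per_lineage": {
            lin: [CLASSES[c] for c in codes]
            for lin, codes in truth.class_per_lineage.items()
        },
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1))


def config_from_dict(d: dict) -> SimulationConfig:
    known = {f for f in SimulationConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    cfg = SimulationConfig(**d)
    if isinstance(cfg.tissues, list):
        cfg.tissues = tuple(cfg.tissues)
    return cfg
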