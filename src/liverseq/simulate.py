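"""Synthetic data with the statistical structure the pipeline assumes.

Three generators:

* :func:`simulate_counts` — negative-binomial bulk RNA-seq counts over a
  donor-liver design (PRE baseline plus DBD/DCD donors followed through
  cold storage), with gene-wise dispersion, log-normal library sizes,
  per-batch location/scale effects, a planted DE gene set, and optional
  per-subject sign-flipped ("inconsistent") donors.  Ground truth is
  returned so recovery tests can score the pipeline.
* :func:`simulate_ontology` — a small rooted DAG of terms (child -> parent
  edges, guaranteed diamond motif) with random gene annotations.
* :func:`simulate_donor_energetics` — per-donor metabolite time courses and
  bivariate (ATP, peak AST) values with a target correlation.

The defaults mirror the study design the pipeline targets: 4 PRE donors,
10 DBD and 6 DCD donors sampled at 0/3/6 h of cold storage, 4 sequencing
batches, ~17,000 expressed genes and ~16.5 million counts per library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import CountMatrix


@dataclass
class SimDesign:
    """Parameters of the count simulation.

    The condition tested for differential expression is group membership:
    planted effects apply to all post-perfusion samples of DE genes in the
    ``de_group`` (log2 scale), so a PRE-vs-``de_group`` contrast at 0h and
    paired storage contrasts both see the intended structure.
    """

    n_genes: int = 17_000
    n_pre: int = 4
    n_dbd: int = 10
    n_dcd: int = 6
    storage_timepoints: tuple = ("0h", "3h", "6h")
    n_batches: int = 4
    mean_library_size: float = 16.5e6
    library_log_sd: float = 0.4
    fraction_de: float = 0.1
    de_group: str = "DCD"
    effect_mean: float = 2.0      # |log2FC| location of planted effects
    effect_sd: float = 0.5
    donor_bio_sd: float = 0.4     # between-donor biological log2 sd, shared
                                  # across one donor's timepoints
    dispersion_log_mean: float = float(np.log(0.01))
    dispersion_log_sd: float = 0.5
    batch_gamma_sd: float = 0.5   # log2 location shifts per batch
    batch_delta_log_sd: float = 0.25  # log of per-batch noise-scale multiplier
    batch_noise_sd: float = 0.15  # baseline log2 within-batch noise scaled by delta_b
    inconsistent_subject_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        # YAML 1.1 reads bare exponents ("2.0e5") as strings; coerce
        for name in ("mean_library_size", "library_log_sd", "fraction_de",
                     "effect_mean", "effect_sd", "donor_bio_sd",
                     "dispersion_log_mean", "dispersion_log_sd",
                     "batch_gamma_sd", "batch_delta_log_sd", "batch_noise_sd",
                     "inconsistent_subject_fraction"):
            setattr(self, name, float(getattr(self, name)))
        for name in ("n_genes", "n_pre", "n_dbd", "n_dcd", "n_batches", "seed"):
            setattr(self, name, int(getattr(self, name)))
        for name in ("fraction_de", "inconsistent_subject_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_genes", "n_pre", "n_dbd", "n_dcd", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SimulationTruth:
    """Everything planted by :func:`simulate_counts`."""

    de_genes: dict                      # gene -> signed log2 effect
    dispersions: pd.Series              # gene -> phi
    baseline_q: pd.Series               # gene -> relative abundance q_g
    library_sizes: pd.Series            # sample -> L_j
    batch_gamma: pd.Series              # batch -> log2 shift
    batch_delta: pd.Series              # batch -> noise-scale multiplier
    flipped: list = field(default_factory=list)  # (gene, donor_id) pairs

    def to_dict(self) -> dict:
        return {
            "de_genes": {g: float(e) for g, e in self.de_genes.items()},
            "dispersions": {g: float(v) for g, v in self.dispersions.items()},
            "baseline_q": {g: float(v) for g, v in self.baseline_q.items()},
            "library_sizes": {s: int(v) for s, v in self.library_sizes.items()},
            "batch_gamma": {str(b): float(v) for b, v in self.batch_gamma.items()},
            "batch_delta": {str(b): float(v) for b, v in self.batch_delta.items()},
            "flipped": [[g, d] for g, d in self.flipped],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        return cls(
            de_genes=dict(d["de_genes"]),
            dispersions=pd.Series(d["dispersions"], dtype=float),
            baseline_q=pd.Series(d["baseline_q"], dtype=float),
            library_sizes=pd.Series(d["library_sizes"], dtype=float),
            batch_gamma=pd.Series(d["batch_gamma"], dtype=float),
            batch_delta=pd.Series(d["batch_delta"], dtype=float),
            flipped=[tuple(x) for x in d.get("flipped", [])],
        )


def _build_metadata(design: SimDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(design.n_pre):
        rows.append((f"PRE{i + 1}", f"preD{i + 1}", "PRE", "pre"))
    for i in range(design.n_dbd):
        for tp in design.storage_timepoints:
            rows.append((f"DBD{i + 1}_{tp}", f"dbdD{i + 1}", "DBD", tp))
    for i in range(design.n_dcd):
        for tp in design.storage_timepoints:
            rows.append((f"DCD{i + 1}_{tp}", f"dcdD{i + 1}", "DCD", tp))
    meta = pd.DataFrame(rows, columns=["sample_id", "donor_id", "group", "timepoint"])
    meta = meta.set_index("sample_id")
    # batches assigned per donor so cold-storage pairs share a batch,
    # mirroring samples of one organ being sequenced together
    donors = meta["donor_id"].unique()
    donor_batch = {d: f"b{rng.integers(1, design.n_batches + 1)}" for d in donors}
    meta["batch"] = meta["donor_id"].map(donor_batch)
    return meta


def simulate_counts(design: SimDesign) -> tuple[CountMatrix, SimulationTruth]:
    """Draw an NB count matrix under ``design`` and record the ground truth.

    The mean model for gene g in sample j is

        mu_gj = L_j * q_g * 2**(effect_gj + gamma_b(j) + noise_gj)

    with ``effect_gj`` the planted log2 effect when sample j is a
    post-perfusion sample of the DE group (sign flipped for donors flagged
    inconsistent), ``gamma_b`` the batch location shift and ``noise_gj``
    zero-mean Gaussian log2 noise whose scale is the batch's delta_b times
    ``batch_noise_sd``.  Counts are NB with variance mu + phi_g * mu^2.
    """
    rng = np.random.default_rng(design.seed)
    meta = _build_metadata(design, rng)
    n_samples = len(meta)
    genes = pd.Index([f"g{i:05d}" for i in range(design.n_genes)], name="gene")

    # baseline relative abundances q_g: heavy-tailed, normalized to sum 1
    q = rng.lognormal(mean=0.0, sigma=1.6, size=design.n_genes)
    q /= q.sum()

    phi = rng.lognormal(design.dispersion_log_mean, design.dispersion_log_sd,
                        size=design.n_genes)
    lib = rng.lognormal(np.log(design.mean_library_size) - design.library_log_sd ** 2 / 2,
                        design.library_log_sd, size=n_samples)
    lib = np.round(lib).astype(np.int64)

    batches = [f"b{i}" for i in range(1, design.n_batches + 1)]
    gamma = pd.Series(rng.normal(0.0, design.batch_gamma_sd, size=design.n_batches),
                      index=batches)
    delta = pd.Series(rng.lognormal(0.0, design.batch_delta_log_sd, size=design.n_batches),
                      index=batches)

    n_de = int(round(design.fraction_de * design.n_genes))
    de_idx = rng.choice(design.n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    magnitudes = np.abs(rng.normal(design.effect_mean, design.effect_sd, size=n_de))
    effects = signs * magnitudes
    de_genes = {genes[i]: float(e) for i, e in zip(de_idx, effects)}

    de_donors = sorted(meta.loc[meta["group"] == design.de_group, "donor_id"].unique())
    flipped: list[tuple[str, str]] = []
    n_flip = int(round(design.inconsistent_subject_fraction * n_de))
    if n_flip and not de_donors:
        raise ValueError("cannot flip donors: no donors in the DE group")
    flip_gene_pos = rng.choice(n_de, size=n_flip, replace=False) if n_flip else []
    for pos in flip_gene_pos:
        donor = de_donors[rng.integers(len(de_donors))]
        flipped.append((genes[de_idx[pos]], donor))
    flipped_map: dict[str, str] = dict(flipped)

    donor_ids = meta["donor_id"].to_numpy()
    donors = meta["donor_id"].unique()
    # gene x donor biological effects: a donor's timepoint samples share one
    # biological state, so paired within-donor contrasts see only the
    # residual NB dispersion while between-donor contrasts see this too
    bio = rng.normal(0.0, design.donor_bio_sd, size=(design.n_genes, len(donors))) \
        if design.donor_bio_sd > 0 else np.zeros((design.n_genes, len(donors)))
    donor_pos = pd.Series(np.arange(len(donors)), index=donors)
    bio_per_sample = bio[:, donor_pos.loc[donor_ids].to_numpy()]

    log2_effect = np.zeros((design.n_genes, n_samples))
    treated_mask = (meta["group"] == design.de_group).to_numpy()
    for pos, gi in enumerate(de_idx):
        eff = effects[pos]
        gene = genes[gi]
        per_sample = np.where(treated_mask, eff, 0.0)
        if gene in flipped_map:
            flip_donor = flipped_map[gene]
            per_sample = np.where(treated_mask & (donor_ids == flip_donor), -eff, per_sample)
        log2_effect[gi] = per_sample

    batch_of_sample = meta["batch"].to_numpy()
    gamma_j = gamma.loc[batch_of_sample].to_numpy()
    delta_j = delta.loc[batch_of_sample].to_numpy()
    noise = rng.normal(0.0, 1.0, size=(design.n_genes, n_samples))
    noise *= design.batch_noise_sd * delta_j

    log2_mu = (np.log2(q)[:, None] + np.log2(lib)[None, :]
               + log2_effect + gamma_j[None, :]
               + bio_per_sample + noise)
    mu = np.exp2(log2_mu)

    counts = np.empty((design.n_genes, n_samples), dtype=np.int64)
    phi_col = phi[:, None]
    poisson_rows = phi < 1e-12
    if poisson_rows.any():
        counts[poisson_rows] = rng.poisson(mu[poisson_rows])
    nb_rows = ~poisson_rows
    if nb_rows.any():
        r = 1.0 / phi_col[nb_rows]
        p = r / (r + mu[nb_rows])
        counts[nb_rows] = rng.negative_binomial(r, p)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=meta.index), meta)
    truth = SimulationTruth(
        de_genes=de_genes,
        dispersions=pd.Series(phi, index=genes),
        baseline_q=pd.Series(q, index=genes),
        library_sizes=pd.Series(lib, index=meta.index),
        batch_gamma=gamma,
        batch_delta=delta,
        flipped=flipped,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# ontology fixture generator


def simulate_ontology(n_terms: int, n_genes: int, seed: int = 0,
                      mean_annotations: float = 2.0):
    """Random rooted term DAG plus a gene -> term annotation table.

    Edges point child -> parent.  For ``n_terms >= 6`` one diamond motif
    (a term with two parents sharing a grandparent) is wired explicitly so
    annotation propagation must de-duplicate. Returns ``(graph, annotations)``
    where annotations is a DataFrame with columns ``gene`` and ``term``.
    """
    if n_terms < 2:
        raise ValueError("need at least 2 terms")
    rng = np.random.default_rng(seed)
    terms = [f"T{i:04d}" for i in range(n_terms)]
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for t in terms:
        g.nodes[t]["name"] = f"term {t}"
    start = 1
    if n_terms >= 6:
        # diamond: T1 and T2 under root, T3 under both T1 and T2
        g.add_edge(terms[1], terms[0])
        g.add_edge(terms[2], terms[0])
        g.add_edge(terms[3], terms[1])
        g.add_edge(terms[3], terms[2])
        start = 4
    for i in range(start, n_terms):
        n_parents = 1 + (rng.random() < 0.2)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            g.add_edge(terms[i], terms[p])

    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    rows = []
    non_root = terms[1:]
    for gene in gene_ids:
        k = rng.poisson(mean_annotations)
        if k == 0:
            continue
        chosen = rng.choice(len(non_root), size=min(k, len(non_root)), replace=False)
        for c in sorted(chosen):
            rows.append((gene, non_root[c]))
    ann = pd.DataFrame(rows, columns=["gene", "term"])
    return g, ann


# ---------------------------------------------------------------------------
# donor energetics generator

DEFAULT_GROUP_MEANS = {
    # metabolite -> group -> per-timepoint means at (pre, 0h, 3h, 6h);
    # micromol per g wet mass, shaped after the declining-ATP / rising-
    # hypoxanthine pattern of ischemic livers (DCD far lower at 0h)
    "ATP": {"DBD": [2.5, 2.0, 1.2, 0.7], "DCD": [2.5, 0.5, 0.3, 0.2]},
    "ADP": {"DBD": [1.8, 1.7, 1.1, 0.8], "DCD": [1.8, 0.6, 0.4, 0.3]},
    "AMP": {"DBD": [0.8, 1.2, 0.9, 0.6], "DCD": [0.8, 1.6, 1.2, 0.9]},
    "hypoxanthine": {"DBD": [0.3, 0.6, 1.0, 1.5], "DCD": [0.3, 1.0, 1.6, 2.2]},
}

ENERGETICS_TIMEPOINTS = ("pre", "0h", "3h", "6h")


def simulate_donor_energetics(n_dbd: int = 6, n_dcd: int = 4,
                              group_means: dict | None = None,
                              rho: float = -0.683,
                              cv: float = 0.25,
                              ast_log_mean: float = np.log(1500.0),
                              ast_log_sd: float = 0.8,
                              n_transplanted: int | None = None,
                              seed: int = 0) -> pd.DataFrame:
    """Per-donor metabolite time courses plus recipient peak AST.

    Metabolite values are log-normal around the group/timepoint means with
    coefficient of variation ``cv``.  For transplanted donors, log peak AST
    is drawn against the standardized pooled log ATP at 0h so the
    (log ATP, log AST) sample correlation targets ``rho`` across groups —
    the group contrast (low-ATP DCD organs, high recipient AST) is part of
    the signal, as in pooled transplant cohorts.  Default rho -0.683 is the
    strength the correlation stage is expected to detect.  Returns a tidy
    DataFrame with one row per donor: ``donor_id, group, transplanted,
    peak_ast`` plus ``<metabolite>_<timepoint>`` columns.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    gm = DEFAULT_GROUP_MEANS if group_means is None else group_means
    for metab, per_group in gm.items():
        for grp, means in per_group.items():
            if any(m < 0 for m in means):
                raise ValueError(f"negative mean for {metab}/{grp}")
    rng = np.random.default_rng(seed)
    donors = [("DBD", f"dbdD{i + 1}") for i in range(n_dbd)] + \
             [("DCD", f"dcdD{i + 1}") for i in range(n_dcd)]
    total = len(donors)
    if n_transplanted is None:
        n_transplanted = total
    transplanted = np.zeros(total, dtype=bool)
    transplanted[rng.choice(total, size=min(n_transplanted, total), replace=False)] = True

    sigma = np.sqrt(np.log(1.0 + cv ** 2))
    rows = []
    for i, (grp, donor) in enumerate(donors):
        row: dict = {"donor_id": donor, "group": grp, "transplanted": bool(transplanted[i])}
        for metab, per_group in gm.items():
            means = per_group[grp]
            for tp, m in zip(ENERGETICS_TIMEPOINTS, means):
                row[f"{metab}_{tp}"] = float(m * np.exp(sigma * rng.normal() - sigma ** 2 / 2))
        rows.append(row)
    table = pd.DataFrame(rows)

    table["peak_ast"] = np.nan
    tx = np.flatnonzero(transplanted)
    if tx.size:
        log_atp = np.log(table.loc[tx, "ATP_0h"].to_numpy())
        spread = log_atp.std()
        u = (log_atp - log_atp.mean()) / spread if spread > 0 else np.zeros(tx.size)
        eps = rng.normal(size=tx.size)
        z = rho * u + np.sqrt(max(0.0, 1.0 - rho ** 2)) * eps
        table.loc[tx, "peak_ast"] = np.exp(ast_log_mean + ast_log_sd * z)
    return table
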