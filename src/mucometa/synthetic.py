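"""Synthetic cohort generator and the toy two-metagenome fixture.

The generator emulates the statistical structure the downstream analysis
assumes: a cohort of cervical-cancer patients whose mucus-associated
metagenomes are mixtures of two latent microbial communities,

* community **A** — mucus/glycan-degrading functions, carried predominantly
  by a Clostridiales-like order, whose share of the metagenome *increases*
  with tumor size (LT-associated);
* community **B** — fast-proliferation functions (ribosome, DNA repair...),
  carried predominantly by a Bacteroidales-like order, dominant in small
  tumors (ST-associated).

Each KO belongs to exactly one community.  Its log2 normalized abundance in
patient *i* is

    x_{k,i} = b_k + log2 w_{c(k),i} + eps_{k,i}

with a per-KO baseline ``b_k`` and within-KO noise ``eps`` chosen so the
marginal over KOs is Normal(mu_c, sigma_c), and the community mixing weight
``w_A,i`` increasing linearly with tumor size (clamped to [0.05, 0.95];
``w_B = 1 - w_A``).  Gene read counts are Poisson around the read mass the
abundance implies, so rare functions drop out of small communities exactly
as they do in real shallowly-covered metagenomes.  Recurrence-free survival
is exponential with hazard increasing in community-A dominance, with
uniform administrative censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .datatypes import CONTIG_COLUMNS
from .errors import InvalidParameterError
from .io import CLINICAL_COLUMNS

# community-specific contig lineages (fixed 7-rank dialect)
LINEAGES_A = [
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Blautia;Blautia coccoides",
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae;Faecalibacterium;Faecalibacterium prausnitzii",
]
LINEAGES_B = [
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Prevotellaceae;Prevotella;Prevotella bivia",
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Bacteroidaceae;Bacteroides;Bacteroides fragilis",
]
LINEAGE_OTHER = (
    "Bacteria;Actinobacteria;Actinomycetia;Bifidobacteriales;"
    "Bifidobacteriaceae;Bifidobacterium;Bifidobacterium longum"
)

ORDER_A = "Clostridiales"
ORDER_B = "Bacteroidales"

GH_FAMILIES = ["GH2", "GH13", "GH18", "GH20", "GH29", "GH33", "GH92", "GH98"]
GT_FAMILIES = ["GT2", "GT4", "GT28", "GT51"]


@dataclass(frozen=True)
class CohortParams:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    Means/sds are on the log2 reads-per-million scale.  ``dominance_slope``
    is the change in community-A mixing weight per cm of tumor size (weights
    clamped to [0.05, 0.95] around 0.5 at the mid-range tumor size).
    ``within_ko_sd`` splits each community's sd into a per-KO baseline part
    and a within-KO across-sample part so a KO is a coherent feature across
    patients rather than white noise.
    """

    n_patients: int = 41
    n_kos_per_community: int = 500
    community_mu_a: float = 2.5
    community_mu_b: float = 5.0
    community_sigma_a: float = 2.6
    community_sigma_b: float = 1.3
    dominance_slope: float = 0.1
    tumor_size_range: tuple[float, float] = (1.8, 11.5)
    read_length: int = 150
    seed: int = 0
    # secondary knobs
    within_ko_sd: float = 0.8
    mean_total_reads: float = 2e7
    hazard_beta: float = 1.2
    baseline_hazard_median_months: float = 15.0
    censor_range_months: tuple[float, float] = (12.0, 60.0)
    major_taxon_fraction: float = 0.85
    n_unannotated_contigs: int = 20
    n_pathways_per_community: int = 5
    cazy_gh_fraction: float = 0.6
    cazy_gt_fraction: float = 0.3

    def validate(self) -> None:
        if self.n_patients < 2:
            raise InvalidParameterError("n_patients must be >= 2")
        if self.n_kos_per_community < 1:
            raise InvalidParameterError("n_kos_per_community must be >= 1")
        if self.community_sigma_a <= 0 or self.community_sigma_b <= 0:
            raise InvalidParameterError("community sigmas must be > 0")
        lo, hi = self.tumor_size_range
        if not lo < hi:
            raise InvalidParameterError("tumor_size_range must satisfy lower < upper")
        if not 0 <= self.within_ko_sd < min(self.community_sigma_a,
                                            self.community_sigma_b):
            raise InvalidParameterError(
                "within_ko_sd must be >= 0 and smaller than both community sigmas"
            )
        if self.read_length < 1:
            raise InvalidParameterError("read_length must be >= 1")


@dataclass
class CohortTruth:
    """Latent state of a generated cohort, for parameter-recovery checks."""

    params: CohortParams
    mixing_weight_a: pd.Series            # per patient, community-A weight
    kos_a: list[str]
    kos_b: list[str]
    pathway_map: dict[str, set[str]]      # pathway_id -> KO set
    cazy_map: dict[str, set[str]]         # ko_id -> CAZy families
    order_a: str = ORDER_A
    order_b: str = ORDER_B

    def community_of(self, ko_id: str) -> str:
        return "A" if ko_id in self._set_a else "B"

    def __post_init__(self):
        self._set_a = set(self.kos_a)

    def expected_curve(self, community: str, samples) -> tuple[float, float]:
        """Implied (mu, sigma) of the community's pooled log2 abundances over
        ``samples``: the per-sample densities are Normal(mu_c + log2 w, sigma_c),
        so the pool is their equal-weight mixture."""
        p = self.params
        if community == "A":
            mu_c, sigma_c = p.community_mu_a, p.community_sigma_a
            w = self.mixing_weight_a.loc[list(samples)]
        else:
            mu_c, sigma_c = p.community_mu_b, p.community_sigma_b
            w = 1.0 - self.mixing_weight_a.loc[list(samples)]
        offsets = np.log2(w.to_numpy())
        mu = mu_c + offsets.mean()
        var = sigma_c**2 + offsets.var()
        return float(mu), float(math.sqrt(var))


def _mixing_weights(params: CohortParams, sizes: np.ndarray) -> np.ndarray:
    lo, hi = params.tumor_size_range
    mid = 0.5 * (lo + hi)
    return np.clip(0.5 + params.dominance_slope * (sizes - mid), 0.05, 0.95)


def generate_cohort(
    params: CohortParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, CohortTruth]:
    """Generate one synthetic cohort.

    Returns
    -------
    contigs : DataFrame
        Per-gene contig-annotation table (:data:`CONTIG_COLUMNS` dialect).
        One contig per detected (sample, KO) occurrence plus a handful of
        unannotated background contigs per sample.
    clinical : DataFrame
        Clinical table indexed by patient_id (age, BMI, FIGO stage, tumor
        size, nodal status, RFS time + event).
    total_reads : Series
        Total sequenced reads per sample.
    truth : CohortTruth
        All latent parameters and per-sample mixing weights.
    """
    params = params or CohortParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    m = params.n_kos_per_community

    patients = [f"P{i + 1:03d}" for i in range(n)]
    lo, hi = params.tumor_size_range
    sizes = np.round(rng.uniform(lo, hi, size=n), 1)
    w_a = _mixing_weights(params, sizes)
    weights = pd.Series(w_a, index=pd.Index(patients, name="patient_id"),
                        name="mixing_weight_a")

    kos_a = [f"K1{i:04d}" for i in range(m)]
    kos_b = [f"K2{i:04d}" for i in range(m)]

    total_reads = pd.Series(
        np.round(params.mean_total_reads
                 * np.exp(rng.normal(0.0, 0.25, size=n))).astype(int),
        index=pd.Index(patients, name="sample_id"), name="total_reads",
    )

    contig_frames = []
    for community, kos, mu_c, sigma_c in (
        ("A", kos_a, params.community_mu_a, params.community_sigma_a),
        ("B", kos_b, params.community_mu_b, params.community_sigma_b),
    ):
        base_sd = math.sqrt(sigma_c**2 - params.within_ko_sd**2)
        baselines = rng.normal(mu_c, base_sd, size=m)
        w = w_a if community == "A" else 1.0 - w_a
        # (KO x patient) log2 RPM
        log2_abund = (
            baselines[:, None]
            + np.log2(w)[None, :]
            + rng.normal(0.0, params.within_ko_sd, size=(m, n))
        )
        lam = 2.0**log2_abund * (total_reads.to_numpy()[None, :] / 1e6)
        reads = rng.poisson(lam)
        ko_idx, pat_idx = np.nonzero(reads)
        read_count = reads[ko_idx, pat_idx]
        lengths = rng.integers(1000, 5001, size=len(ko_idx))
        depth = np.round(read_count * params.read_length / lengths, 4)
        major = LINEAGES_A if community == "A" else LINEAGES_B
        minor = LINEAGES_B if community == "A" else LINEAGES_A
        pick = rng.random(len(ko_idx))
        half = params.major_taxon_fraction / 2
        lineage = np.where(
            pick < half, major[0],
            np.where(pick < 2 * half, major[1],
                     np.where(pick < params.major_taxon_fraction
                              + (1 - params.major_taxon_fraction) / 2,
                              minor[0], minor[1])),
        )
        ko_arr = np.asarray(kos, dtype=object)[ko_idx]
        pat_arr = np.asarray(patients, dtype=object)[pat_idx]
        frame = pd.DataFrame({
            "sample_id": pat_arr,
            "contig_id": [f"c_{community}_{k}_{s}" for k, s in zip(ko_arr, pat_arr)],
            "length_bp": lengths,
            "depth": depth,
            "lineage": lineage,
            "gene_id": [f"g_{community}_{k}_{s}" for k, s in zip(ko_arr, pat_arr)],
            "ko_id": ko_arr,
            "read_count": read_count,
        })
        contig_frames.append(frame)

    # unannotated background contigs (no KO call; weight in taxonomy only)
    if params.n_unannotated_contigs > 0:
        rows = []
        for pat in patients:
            lengths = rng.integers(1000, 8001, size=params.n_unannotated_contigs)
            depths = np.round(rng.gamma(2.0, 2.0, size=params.n_unannotated_contigs), 4)
            for j, (L, D) in enumerate(zip(lengths, depths)):
                rows.append((pat, f"c_bg_{pat}_{j}", int(L), float(D),
                             LINEAGE_OTHER, f"g_bg_{pat}_{j}", None, 0))
        contig_frames.append(pd.DataFrame(rows, columns=CONTIG_COLUMNS))

    contigs = pd.concat(contig_frames, ignore_index=True)[CONTIG_COLUMNS]

    # clinical covariates
    age = np.clip(np.round(rng.normal(49, 10, size=n)), 29, 72).astype(int)
    bmi = np.round(np.clip(rng.normal(28.6, 5.0, size=n), 17.5, 46.7), 1)
    p_advanced = 1.0 / (1.0 + np.exp(-(sizes - 6.0) / 1.5))
    advanced = rng.random(n) < p_advanced
    stage = np.where(advanced,
                     np.where(rng.random(n) < 0.8, "III", "IV"),
                     np.where(rng.random(n) < 0.7, "II", "I"))
    node_positive = rng.random(n) < np.clip(0.15 + 0.6 * w_a, 0.0, 1.0)

    lam0 = math.log(2) / params.baseline_hazard_median_months
    hazard = lam0 * np.exp(params.hazard_beta * (w_a - 0.5))
    t_event = rng.exponential(1.0 / hazard)
    c_lo, c_hi = params.censor_range_months
    t_censor = rng.uniform(c_lo, c_hi, size=n)
    rfs_months = np.round(np.minimum(t_event, t_censor), 1)
    rfs_event = t_event <= t_censor

    clinical = pd.DataFrame({
        "patient_id": patients, "age": age, "bmi": bmi, "stage": stage,
        "tumor_size_cm": sizes, "node_positive": node_positive,
        "rfs_months": rfs_months, "rfs_event": rfs_event,
    }, columns=CLINICAL_COLUMNS).set_index("patient_id")

    # synthetic pathway membership: consecutive chunks of each community
    pathway_map: dict[str, set[str]] = {}
    for community, kos in (("A", kos_a), ("B", kos_b)):
        npw = max(1, min(params.n_pathways_per_community, len(kos)))
        for j, chunk in enumerate(np.array_split(np.asarray(kos, dtype=object), npw)):
            pathway_map[f"pw_{community}{j + 1:02d}"] = set(chunk.tolist())

    # CAZy: community A skews glycoside hydrolase, B glycosyl transferase
    cazy_map: dict[str, set[str]] = {}
    for ko in kos_a:
        if rng.random() < params.cazy_gh_fraction:
            cazy_map[ko] = {GH_FAMILIES[rng.integers(len(GH_FAMILIES))]}
    for ko in kos_b:
        if rng.random() < params.cazy_gt_fraction:
            cazy_map[ko] = {GT_FAMILIES[rng.integers(len(GT_FAMILIES))]}

    truth = CohortTruth(params=params, mixing_weight_a=weights,
                        kos_a=kos_a, kos_b=kos_b,
                        pathway_map=pathway_map, cazy_map=cazy_map)
    return contigs, clinical, total_reads, truth


def toy_figs2() -> dict[str, pd.DataFrame]:
    """The two-metagenome toy worked example as contig-annotation frames.

    Two sequenced metagenomes, A and B, populated by 18 and 19 bacterial
    cells of 4 species.  Circle-shaped cells carry function F1, oval-shaped
    cells carry F2, and every gene is covered by exactly one read, so the
    function abundance of F1 is simply the number of circles (4 in A) and
    that of F2 the number of ovals (14 in A, 4 in B).

    The original description of metagenome B is internally inconsistent
    (19 cells stated twice, but per-function counts of 16 and 4 would sum
    to 20); this fixture honors the explicit cell totals and the A-side
    counts, so B carries 15 F1 cells and 4 F2 cells.  B's F1 count is
    therefore a reconstruction, not a quoted value.

    Each cell contributes one 1000-bp contig with one annotated gene plus
    one unannotated gene (ignored by the MFA builder by design).
    """
    species = {  # shape -> two species lineages
        "circle": [
            "Bacteria;Firmicutes;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus;Streptococcus red",
            "Bacteria;Firmicutes;Bacilli;Lactobacillales;Enterococcaceae;Enterococcus;Enterococcus green",
        ],
        "oval": [
            "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Enterobacteriaceae;Escherichia;Escherichia yellow",
            "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Yersiniaceae;Serratia;Serratia blue",
        ],
    }
    counts = {"A": {"circle": 4, "oval": 14}, "B": {"circle": 15, "oval": 4}}
    function_of = {"circle": "F1", "oval": "F2"}
    out = {}
    for metagenome, shape_counts in counts.items():
        rows = []
        cell = 0
        for shape, n_cells in shape_counts.items():
            for i in range(n_cells):
                cell += 1
                cid = f"cell{cell:02d}"
                lineage = species[shape][i % 2]
                rows.append((metagenome, cid, 1000, 0.001, lineage,
                             f"{cid}_gene1", function_of[shape], 1))
                rows.append((metagenome, cid, 1000, 0.001, lineage,
                             f"{cid}_gene2", None, 1))
        out[metagenome] = pd.DataFrame(rows, columns=CONTIG_COLUMNS)
    return out


def truth_to_dict(truth: CohortTruth) -> dict:
    """JSON-serialisable view of the ground-truth record."""
    return {
        "params": asdict(truth.params),
        "mixing_weight_a": truth.mixing_weight_a.to_dict(),
        "kos_a": truth.kos_a,
        "kos_b": truth.kos_b,
        "pathway_map": {k: sorted(v) for k, v in truth.pathway_map.items()},
        "cazy_map": {k: sorted(v) for k, v in truth.cazy_map.items()},
        "order_a": truth.order_a,
        "order_b": truth.order_b,
    }
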