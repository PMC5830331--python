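"""Synthetic matched-cohort generator with known ground truth.

Emulates a cross-sectional exome study of 41 NSAID users and 41 matched
non-users: group-specific negative-binomial mutation loads, per-stratum
mutational-signature mixtures over the 96 trinucleotide channels, clonal
VAF structure (VAF = purity x prevalence / 2 with binomial read
sampling), pathway-specific reductions of functional mutations in users,
and per-class somatic copy-number segments. Every draw comes from one
seeded generator, so outputs are byte-identical across runs.

The default parameter values are the study conditions the generator
emulates: SNV loads 290.93 (SD 209.69) per user vs 402.49 (SD 362.68)
per non-user, indels 17.95 (SD 12.25) vs 22.42 (SD 13.77), >98% epithelial
purity at 80x depth, a 50% user-specific reduction of functional
mutations in nine of 35 cancer-associated pathways, non-user-only focal
amplifications (rate chosen so ~8/41 non-users carry one) and genome
doubling in ~4/41 non-users.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .arms import load_arm_table
from .catalog import FUNCTIONAL_CATEGORIES, NONFUNCTIONAL_CATEGORIES, COLUMNS, PathwayDB
from .spectrum import CHANNELS
from .sca import SEG_COLUMNS, CLASS_CN

__all__ = [
    "CohortTruth",
    "generate_cohort",
    "generate_segments",
    "synthetic_gene_model",
    "synthetic_pathways",
    "default_truth",
    "null_truth",
    "AFFECTED_PATHWAYS",
]

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The nine pathways carrying the user-specific functional-mutation
#: reduction in the default study configuration.
AFFECTED_PATHWAYS = (
    "DNA repair",
    "Apoptosis",
    "Caspase cascade in apoptosis",
    "IFN-gamma pathway",
    "Cellular response to stress",
    "Cell cycle",
    "p53 pathway",
    "VEGFR1 specific signals",
    "DNA replication/Mitotic M-G1 phases",
)

# sizes chosen so each affected pathway carries enough functional burden
# (~3-6 hits per non-user at the default load) for a 41-vs-41 cohort to
# resolve a 50% reduction; matches the scale of the larger cancer pathways
_AFFECTED_SIZES = (180, 170, 150, 140, 200, 250, 160, 140, 220)

# the five dominant processes carry their cohort-wide shares verbatim;
# the remaining 27.6% of mutations come from three background processes
_DEFAULT_WEIGHTS = {
    "S17": 0.315, "S1": 0.205, "S9": 0.078, "S5": 0.071, "S8": 0.055,
    "S2": 0.090, "S3": 0.100, "S13": 0.086,
}

_FUNC_WEIGHTS = (0.75, 0.08, 0.07, 0.06, 0.04)  # over FUNCTIONAL_CATEGORIES
_NONFUNC_GENIC = (
    "exon-synonymous",
    "intron-coding-gene",
    "3'utr-intron",
    "5'utr-intron",
    "upstream-1kb",
    "downstream-1kb",
    "non-coding-RNA-exon",
    "non-coding-RNA-intron",
)
_NONFUNC_WEIGHTS = (0.12, 0.45, 0.08, 0.06, 0.12, 0.12, 0.03, 0.02)


@dataclass
class CohortTruth:
    """Hidden parameters of a synthetic cohort (recovery-test ground truth)."""

    n_per_group: int = 41
    load_mean_user: float = 290.93
    load_sd_user: float = 209.69
    load_mean_nonuser: float = 402.49
    load_sd_nonuser: float = 362.68
    indel_mean_user: float = 17.95
    indel_sd_user: float = 12.25
    indel_mean_nonuser: float = 22.42
    indel_sd_nonuser: float = 13.77
    purity: float = 0.98
    depth: int = 80
    target_mb: float = 96.0
    frac_smoker: float = 0.5
    tp53_rate_user: float = 6 / 41
    tp53_rate_nonuser: float = 11 / 41
    #: exponent of the load weight when assigning TP53-mutant status;
    #: > 0 couples TP53 mutation to high mutation load, 0 decouples them
    tp53_load_power: float = 2.0
    signature_weights: dict = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    smoker_s17_factor: float = 2.0
    #: Dirichlet precision for per-patient jitter of signature weights
    #: (mean stays at the stratum weights); 0 gives every patient in a
    #: stratum the identical mixture
    signature_dispersion: float = 25.0
    clone_prevalences: dict = field(
        default_factory=lambda: {
            "user": [(1.0, 0.5), (0.35, 0.3), (0.15, 0.2)],
            "nonuser": [(1.0, 0.5), (0.6, 0.3), (0.25, 0.2)],
        }
    )
    pathway_effects: dict = field(
        default_factory=lambda: {p: 0.5 for p in AFFECTED_PATHWAYS}
    )
    gene_effects: dict = field(default_factory=dict)
    gene_weights: dict = field(default_factory=dict)  # gene -> relative draw weight
    frac_genic: float = 0.9
    frac_functional: float = 0.35
    sca_rates: dict = field(
        default_factory=lambda: {
            "user": {
                "HD": 0.25,
                "loss": 1.1,
                "cnLOH": 1.0,
                "balanced_gain": 0.35,
                "allele_gain": 0.6,
                "focal_amp": 0.0,
            },
            "nonuser": {
                "HD": 0.3,
                "loss": 1.5,
                "cnLOH": 1.5,
                "balanced_gain": 0.5,
                "allele_gain": 0.8,
                "focal_amp": 0.217,
            },
        }
    )
    wgd_prob_user: float = 0.0
    wgd_prob_nonuser: float = 4 / 41
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "load_mean_user", "load_sd_user", "load_mean_nonuser", "load_sd_nonuser",
            "indel_mean_user", "indel_sd_user", "indel_mean_nonuser", "indel_sd_nonuser",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.purity <= 1):
            raise ValueError("purity must lie in (0, 1]")
        w = sum(self.signature_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"signature weights must sum to 1 (got {w})")
        for group, clones in self.clone_prevalences.items():
            for prev, frac in clones:
                if not (0 < prev <= 1):
                    raise ValueError(f"clone prevalence out of (0,1] in {group}")
            total = sum(frac for _, frac in clones)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"clone mutation fractions must sum to 1 in {group}")
        for pw, red in self.pathway_effects.items():
            if not (0 <= red <= 1):
                raise ValueError(f"pathway effect for {pw!r} outside [0,1]")
        for group, rates in self.sca_rates.items():
            for cls, rate in rates.items():
                if rate < 0:
                    raise ValueError(f"negative SCA rate {cls} in {group}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clone_prevalences"] = {
            g: [list(c) for c in cl] for g, cl in self.clone_prevalences.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortTruth":
        d = dict(d)
        if "clone_prevalences" in d:
            d["clone_prevalences"] = {
                g: [tuple(c) for c in cl] for g, cl in d["clone_prevalences"].items()
            }
        return cls(**d)


def default_truth(**overrides) -> CohortTruth:
    """The default study configuration, with optional field overrides."""
    t = CohortTruth(**overrides)
    t.validate()
    return t


def null_truth(load_mean: float = 290.93, load_sd: float = 209.69, **overrides) -> CohortTruth:
    """Exchangeable-groups configuration: no effect of any kind.

    Both groups share mutation load, clone structure, SCA rates and
    signature mixture (smoking still varies spectra, but identically in
    the two groups).
    """
    clones = [(1.0, 0.5), (0.4, 0.3), (0.2, 0.2)]
    rates = {
        "HD": 0.3, "loss": 1.2, "cnLOH": 1.2,
        "balanced_gain": 0.4, "allele_gain": 0.7, "focal_amp": 0.1,
    }
    kw = dict(
        load_mean_user=load_mean,
        load_sd_user=load_sd,
        load_mean_nonuser=load_mean,
        load_sd_nonuser=load_sd,
        indel_mean_user=18.0,
        indel_sd_user=12.0,
        indel_mean_nonuser=18.0,
        indel_sd_nonuser=12.0,
        tp53_rate_user=0.2,
        tp53_rate_nonuser=0.2,
        tp53_load_power=0.0,
        clone_prevalences={"user": list(clones), "nonuser": list(clones)},
        pathway_effects={},
        gene_effects={},
        sca_rates={"user": dict(rates), "nonuser": dict(rates)},
        wgd_prob_user=0.0,
        wgd_prob_nonuser=0.0,
    )
    kw.update(overrides)
    t = CohortTruth(**kw)
    t.validate()
    return t


# ---------------------------------------------------------------------------
# genome annotation fixtures (deterministic)


def synthetic_gene_model(
    n_genes: int = 4000, gene_length: int = 10_000, arm_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Evenly spaced synthetic genes across the autosomal arms.

    Columns: gene, chrom, start, end (0-based half-open). Deterministic
    (no randomness): genes are placed on an even grid per arm, counts
    proportional to arm length.
    """
    if arm_table is None:
        arm_table = load_arm_table()
    total = arm_table["length_mb"].sum()
    rows = []
    gid = 0
    for row in arm_table.itertuples(index=False):
        k = max(1, int(round(n_genes * row.length_mb / total)))
        span = row.end - row.start
        step = span / k
        for i in range(k):
            centre = row.start + (i + 0.5) * step
            start = int(centre - gene_length / 2)
            end = start + gene_length
            if start < row.start or end > row.end:
                continue
            gid += 1
            rows.append({"gene": f"BEG{gid:04d}", "chrom": row.chrom,
                         "start": start, "end": end})
    return pd.DataFrame(rows)


def synthetic_pathways(
    gene_model: pd.DataFrame, n_pathways: int = 35, seed: int = 2018
) -> PathwayDB:
    """35 synthetic pathways; the nine 'affected' ones sized 80-250 genes.

    The nine affected pathways may overlap one another; the remaining
    pathways are drawn from the complement gene pool so that a pathway
    carrying no injected effect is genuinely null in recovery tests.
    """
    rng = np.random.default_rng(seed)
    genes = gene_model["gene"].to_numpy()
    pathways: dict[str, set[str]] = {}
    for name, size in zip(AFFECTED_PATHWAYS, _AFFECTED_SIZES):
        pathways[name] = set(rng.choice(genes, size=size, replace=False))
    affected_genes: set[str] = set().union(*pathways.values())
    rest = np.array(sorted(set(genes) - affected_genes))
    for j in range(len(AFFECTED_PATHWAYS), n_pathways):
        size = int(rng.integers(20, 300))
        pathways[f"Pathway_{j + 1:02d}"] = set(rng.choice(rest, size=size, replace=False))
    return PathwayDB(pathways)


# ---------------------------------------------------------------------------
# sampling helpers


def _nb_counts(rng, mean: float, sd: float, size: int) -> np.ndarray:
    var = sd * sd
    if var <= mean:
        warnings.warn(
            f"negative-binomial with var <= mean ({var:.1f} <= {mean:.1f}); "
            "falling back to Poisson",
            stacklevel=2,
        )
        return rng.poisson(mean, size=size)
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _smoker_weights(weights: dict, factor: float) -> dict:
    w = dict(weights)
    if "S17" in w and factor != 1.0:
        w["S17"] *= factor
        total = sum(w.values())
        w = {k: v / total for k, v in w.items()}
    return w


# per-channel pyrimidine-strand and purine-strand (ref, alt, context3)
_CHAN_PYR = []
_CHAN_PUR = []
for _lab in CHANNELS:
    _ref, _alt = _lab[2], _lab[4]
    _ctx = _lab[0] + _ref + _lab[6]
    _CHAN_PYR.append((_ref, _alt, _ctx))
    _CHAN_PUR.append(
        (_COMPL[_ref], _COMPL[_alt], "".join(_COMPL[b] for b in reversed(_ctx)))
    )
_PYR = {k: np.array([t[i] for t in _CHAN_PYR]) for i, k in enumerate(("ref", "alt", "ctx"))}
_PUR = {k: np.array([t[i] for t in _CHAN_PUR]) for i, k in enumerate(("ref", "alt", "ctx"))}


def _channel_to_snv(rng, chan_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand channel indices into (ref, alt, context3) with random strand."""
    flip = rng.random(len(chan_idx)) < 0.5
    refs = np.where(flip, _PUR["ref"][chan_idx], _PYR["ref"][chan_idx])
    alts = np.where(flip, _PUR["alt"][chan_idx], _PYR["alt"][chan_idx])
    ctxs = np.where(flip, _PUR["ctx"][chan_idx], _PYR["ctx"][chan_idx])
    return refs, alts, ctxs


# ---------------------------------------------------------------------------
# main generator


def generate_cohort(
    truth: CohortTruth,
    pathways: PathwayDB | None = None,
    signatures: pd.DataFrame | None = None,
    gene_model: pd.DataFrame | None = None,
    arm_table: pd.DataFrame | None = None,
):
    """Generate (catalog, meta, segments, truth_log) for one cohort.

    ``signatures`` is a 96xK column-stochastic DataFrame; defaults to the
    packaged synthetic reference set. Fully reproducible from
    ``truth.seed``.
    """
    from .refsigs import load_reference_signatures

    truth.validate()
    if signatures is None:
        signatures = load_reference_signatures()
    if not np.allclose(signatures.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("signature matrix columns must each sum to 1")
    if arm_table is None:
        arm_table = load_arm_table()
    if gene_model is None:
        gene_model = synthetic_gene_model(arm_table=arm_table)
    if pathways is None:
        pathways = synthetic_pathways(gene_model)
    missing = set(truth.pathway_effects) - set(pathways.names)
    if missing:
        raise ValueError(f"pathway_effects name(s) not in PathwayDB: {sorted(missing)}")

    rng = np.random.default_rng(truth.seed)
    n = truth.n_per_group
    patient_ids = [f"U{i + 1:03d}" for i in range(n)] + [f"N{i + 1:03d}" for i in range(n)]
    is_user = np.array([True] * n + [False] * n)

    # smoking matched across groups: same smoker count in each group
    k_smoke = int(round(truth.frac_smoker * n))
    smoker = np.zeros(2 * n, dtype=bool)
    smoker[rng.permutation(n)[:k_smoke]] = True
    smoker[n + rng.permutation(n)[:k_smoke]] = True

    # mutation loads
    snv_load = np.empty(2 * n, dtype=int)
    indel_load = np.empty(2 * n, dtype=int)
    snv_load[:n] = _nb_counts(rng, truth.load_mean_user, truth.load_sd_user, n)
    snv_load[n:] = _nb_counts(rng, truth.load_mean_nonuser, truth.load_sd_nonuser, n)
    indel_load[:n] = _nb_counts(rng, truth.indel_mean_user, truth.indel_sd_user, n)
    indel_load[n:] = _nb_counts(rng, truth.indel_mean_nonuser, truth.indel_sd_nonuser, n)
    snv_load = np.maximum(snv_load, 1)

    # TP53 status rank-correlated with load (keeps group means at target)
    tp53 = np.zeros(2 * n, dtype=bool)
    total_load = (snv_load + indel_load).astype(float)
    for lo, hi, rate in ((0, n, truth.tp53_rate_user), (n, 2 * n, truth.tp53_rate_nonuser)):
        k = int(round(rate * n))
        if k > 0:
            w = total_load[lo:hi] ** truth.tp53_load_power
            pick = rng.choice(np.arange(lo, hi), size=k, replace=False, p=w / w.sum())
            tp53[pick] = True

    meta = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "nsaid_user": is_user,
            "ever_smoker": smoker,
            "tp53_mutant": tp53,
            "target_mb": truth.target_mb,
        }
    )

    # per-stratum signature weights, with optional per-patient jitter
    smoker_w = _smoker_weights(truth.signature_weights, truth.smoker_s17_factor)
    sig_names = list(truth.signature_weights)
    ref_block = signatures[sig_names].to_numpy()

    def patient_mix(weights: dict) -> np.ndarray:
        w = np.array([weights[s] for s in sig_names])
        if truth.signature_dispersion > 0 and len(w) > 1:
            w = rng.dirichlet(truth.signature_dispersion * w)
        v = ref_block @ w
        return v / v.sum()

    # draw SNV channels per patient
    chan_parts, pid_parts = [], []
    for i, pid in enumerate(patient_ids):
        mix = patient_mix(smoker_w if smoker[i] else truth.signature_weights)
        counts = rng.multinomial(snv_load[i], mix)
        chan_parts.append(np.repeat(np.arange(96), counts))
        pid_parts.append(np.full(snv_load[i], i, dtype=int))
    chan_idx = np.concatenate(chan_parts)
    snv_owner = np.concatenate(pid_parts)
    refs, alts, ctxs = _channel_to_snv(rng, chan_idx)

    # indel rows
    indel_owner = np.repeat(np.arange(2 * n), indel_load)
    n_snv, n_indel = len(snv_owner), len(indel_owner)
    n_mut = n_snv + n_indel
    owner = np.concatenate([snv_owner, indel_owner])
    mut_type = np.concatenate(
        [
            np.full(n_snv, "SNV"),
            rng.choice(["INS", "DEL"], size=n_indel),
        ]
    )

    # genomic placement: genic (within 1 kb of a gene) or intergenic
    g_chrom = gene_model["chrom"].to_numpy()
    g_start = gene_model["start"].to_numpy()
    g_end = gene_model["end"].to_numpy()
    g_name = gene_model["gene"].to_numpy()
    n_genes = len(gene_model)

    genic = rng.random(n_mut) < truth.frac_genic
    gene_idx = np.full(n_mut, -1, dtype=int)
    if truth.gene_weights:
        gw = np.ones(n_genes)
        gidx_by_name = {g: i for i, g in enumerate(g_name)}
        for g, w in truth.gene_weights.items():
            if g in gidx_by_name:
                gw[gidx_by_name[g]] = w
        gene_idx[genic] = rng.choice(n_genes, size=int(genic.sum()), p=gw / gw.sum())
    else:
        gene_idx[genic] = rng.integers(0, n_genes, size=int(genic.sum()))

    # user-specific pathway/gene effects: suppressed functional hits are
    # reassigned to pathway-free genes so total loads stay at target
    func_draw = rng.random(n_mut) < truth.frac_functional
    functional = genic & func_draw

    gene_reduction = {}
    for pw, red in truth.pathway_effects.items():
        for g in pathways[pw]:
            gene_reduction[g] = max(gene_reduction.get(g, 0.0), red)
    for g, red in truth.gene_effects.items():
        gene_reduction[g] = max(gene_reduction.get(g, 0.0), red)
    if gene_reduction:
        pool = np.nonzero(~np.isin(g_name, list(pathways.all_genes())
                                   + list(truth.gene_effects)))[0]
        if len(pool) == 0:
            raise ValueError("no pathway-free genes available for reassignment")
        red_by_idx = np.zeros(n_genes)
        name_to_idx = {g: i for i, g in enumerate(g_name)}
        for g, red in gene_reduction.items():
            if g in name_to_idx:
                red_by_idx[name_to_idx[g]] = red
        candidates = functional & is_user[owner] & (gene_idx >= 0)
        hit_red = np.where(candidates, red_by_idx[np.maximum(gene_idx, 0)], 0.0)
        move = rng.random(n_mut) < hit_red
        gene_idx[move] = rng.choice(pool, size=int(move.sum()))

    # positions
    pos = np.empty(n_mut, dtype=np.int64)
    chrom = np.empty(n_mut, dtype=object)
    gmask = gene_idx >= 0
    gi = gene_idx[gmask]
    lo = g_start[gi] - 1000
    hi = g_end[gi] + 1000
    pos[gmask] = rng.integers(lo, hi) + 1  # 1-based
    chrom[gmask] = g_chrom[gi]
    n_inter = int((~gmask).sum())
    if n_inter:
        arm_p = (arm_table["length_mb"] / arm_table["length_mb"].sum()).to_numpy()
        arm_pick = rng.choice(len(arm_table), size=n_inter, p=arm_p)
        a_start = arm_table["start"].to_numpy()[arm_pick]
        a_end = arm_table["end"].to_numpy()[arm_pick]
        pos[~gmask] = rng.integers(a_start, a_end) + 1
        chrom[~gmask] = arm_table["chrom"].to_numpy()[arm_pick]

    # categories
    category = np.empty(n_mut, dtype=object)
    category[~gmask] = "intergenic-near-capture"
    ng = int(gmask.sum())
    func_g = functional[gmask]
    cats_g = np.empty(ng, dtype=object)
    cats_g[func_g] = rng.choice(
        FUNCTIONAL_CATEGORIES, size=int(func_g.sum()), p=_FUNC_WEIGHTS
    )
    cats_g[~func_g] = rng.choice(
        _NONFUNC_GENIC, size=int((~func_g).sum()), p=_NONFUNC_WEIGHTS
    )
    category[gmask] = cats_g

    # clonal structure and VAF
    vaf = np.empty(n_mut)
    clone_cfg = {
        True: truth.clone_prevalences["user"],
        False: truth.clone_prevalences["nonuser"],
    }
    for user_flag, clones in clone_cfg.items():
        sel = is_user[owner] == user_flag
        m = int(sel.sum())
        prevs = np.array([c[0] for c in clones])
        fracs = np.array([c[1] for c in clones])
        which = rng.choice(len(clones), size=m, p=fracs)
        true_vaf = truth.purity * prevs[which] / 2.0
        reads = rng.binomial(truth.depth, true_vaf)
        vaf[sel] = np.maximum(reads, 1) / truth.depth
    vaf = np.clip(vaf, None, 1.0)

    # copy-number segments and the diploid-balanced flag
    seg_frames = []
    diploid_balanced = np.ones(n_mut, dtype=bool)
    for i, pid in enumerate(patient_ids):
        group = "user" if is_user[i] else "nonuser"
        wgd_p = truth.wgd_prob_user if is_user[i] else truth.wgd_prob_nonuser
        segs = generate_segments(
            pid, truth.sca_rates[group], arm_table, rng, wgd=rng.random() < wgd_p
        )
        if len(segs):
            seg_frames.append(segs)
            mine = owner == i
            mpos = pos[mine] - 1
            mchrom = chrom[mine]
            flag = diploid_balanced[mine]
            for s in segs.itertuples(index=False):
                inside = (mchrom == s.chrom) & (mpos >= s.start) & (mpos < s.end)
                flag[inside] = False
            diploid_balanced[mine] = flag

    segments = (
        pd.concat(seg_frames, ignore_index=True)
        if seg_frames
        else pd.DataFrame(columns=SEG_COLUMNS)
    )

    # SNV ref/alt/context; indels get simple one-base events
    ref_all = np.empty(n_mut, dtype=object)
    alt_all = np.empty(n_mut, dtype=object)
    ctx_all = np.empty(n_mut, dtype=object)
    ref_all[:n_snv], alt_all[:n_snv], ctx_all[:n_snv] = refs, alts, ctxs
    ins = mut_type == "INS"
    dele = mut_type == "DEL"
    ref_all[ins], alt_all[ins] = "A", "AT"
    ref_all[dele], alt_all[dele] = "AT", "A"
    ctx_all[n_snv:] = ""

    catalog = pd.DataFrame(
        {
            "patient_id": np.array(patient_ids, dtype=object)[owner],
            "chrom": chrom,
            "pos": pos,
            "ref": ref_all,
            "alt": alt_all,
            "mut_type": mut_type,
            "context3": ctx_all,
            "vaf": vaf,
            "genes": np.where(gmask, g_name[np.maximum(gene_idx, 0)], ""),
            "category": category,
        },
        columns=COLUMNS,
    )
    catalog["diploid_balanced"] = diploid_balanced
    catalog = catalog.sort_values(
        ["patient_id", "chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)

    truth_log = {
        "truth": truth.to_dict(),
        "n_snv": int(n_snv),
        "n_indel": int(n_indel),
        "smoker_ids": [patient_ids[i] for i in np.nonzero(smoker)[0]],
        "tp53_ids": [patient_ids[i] for i in np.nonzero(tp53)[0]],
    }
    return catalog, meta, segments, truth_log


_SEG_LEN = {"focal_amp": (500_000, 2_500_000)}


def generate_segments(
    patient_id: str,
    sca_rates: dict,
    arm_table: pd.DataFrame,
    rng: np.random.Generator | None = None,
    wgd: bool = False,
    max_tries: int = 25,
) -> pd.DataFrame:
    """Draw non-overlapping true copy-number segments for one patient.

    Per-class counts are Poisson with the given rates; focal
    amplifications are short (<= 2.5 Mb), other classes are broad
    (lognormal around ~12 Mb). ``wgd=True`` adds a whole-genome
    balanced-gain state on top. The rest of the genome is implicitly
    diploid-balanced.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    placed: dict[str, list[tuple[int, int]]] = {}
    if wgd:
        for a in arm_table.itertuples(index=False):
            rows.append((patient_id, a.chrom, a.start, a.end, 4, 2, "balanced_gain"))
            placed.setdefault(a.chrom, []).append((a.start, a.end))
    arm_p = (arm_table["length_mb"] / arm_table["length_mb"].sum()).to_numpy()
    for cls, rate in sca_rates.items():
        if cls not in CLASS_CN:
            raise ValueError(f"unknown SCA class {cls!r}")
        if rate < 0:
            raise ValueError("SCA rates must be >= 0")
        count = rng.poisson(rate)
        total_cn, minor_cn = CLASS_CN[cls]
        for _ in range(count):
            for _try in range(max_tries):
                a = arm_table.iloc[rng.choice(len(arm_table), p=arm_p)]
                if cls == "focal_amp":
                    length = int(rng.integers(*_SEG_LEN["focal_amp"]))
                else:
                    length = int(np.clip(rng.lognormal(np.log(12e6), 0.6), 2e6, 4e7))
                length = min(length, int(a.end - a.start))
                start = int(rng.integers(a.start, a.end - length + 1))
                end = start + length
                if all(
                    end <= s or start >= e for s, e in placed.get(a.chrom, [])
                ):
                    placed.setdefault(a.chrom, []).append((start, end))
                    rows.append((patient_id, a.chrom, start, end, total_cn, minor_cn, cls))
                    break
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "chrom", "start", "end", "total_cn", "minor_cn", "class"],
    )
    for col, val in (("n_probes", np.nan), ("log_ratio", np.nan)):
        df[col] = val
    return df[SEG_COLUMNS]


def write_truth(truth_log: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_log, fh, indent=2)
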