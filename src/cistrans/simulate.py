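"""Synthetic MPRA studies with known ground truth.

The generator emulates the statistical structure of a two-species reporter
study: orthologous human/mouse TSS pairs measured in human and mouse ESC
environments, with

* per-(sequence, environment) true log2 activities ``alpha*`` built additively
  from a pair baseline, planted motif contributions, a planted cis shift
  (applied to the mouse sequence in both environments), and a planted trans
  shift (applied to both sequences in the mESC environment);
* negative-binomial barcode counts whose RNA/DNA ratio encodes ``alpha*``;
* inactive random negative controls (3 barcodes each) pinned at the global
  minimum activity and high-activity positive-control tiles (60 barcodes
  each) whose activity is environment-independent — making their down-sampled
  pseudo-pairs true nulls on every differential axis;
* 144-bp sequences with exact-consensus motif insertions, where "disruption"
  means the motif was planted in exactly one member of a pair;
* a TAD-partitioned expression matrix in which planted "redundant" enhancers
  share a latent factor with their focal element;
* a TF differential-expression table whose log2 fold changes match the signs
  of the planted trans motifs.

The additive construction makes the truth exactly recoverable:
``native* = cis* + trans*`` holds for every pair, and compensatory pairs have
oppositely signed cis and trans truths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd

from cistrans.config import BIOTYPES, ENVIRONMENTS, SPECIES, ConfigurationError, SimulationConfig
from cistrans.library_design import TILE_LENGTH, assign_barcodes

MOTIF_WIDTH = 8
#: probability that an activity motif is placed in a pair / disrupted given
#: placed in a cis-effect pair
MOTIF_PLACEMENT_PROB = 0.30
MOTIF_DISRUPTION_PROB = 0.40
#: trans-motif placement probability in direction-matched trans-effect pairs
#: vs background
TRANS_MOTIF_MATCHED_PROB = 0.50
TRANS_MOTIF_BACKGROUND_PROB = 0.10
#: planted cis/trans effects have at least this log2 magnitude, so the
#: configured fractions describe real, detectable divergence rather than
#: arbitrarily small shifts
MIN_PLANTED_EFFECT = 0.3
POSITIVE_CONTROL_ALPHA = 5.0

_BASES = np.array(list("ACGT"))


@dataclass
class GroundTruth:
    """Planted parameters of one simulated study.

    ``alpha`` holds the true log2 activity of every element in each
    environment; ``pairs`` the true cis, trans and native effect of every
    orthologous pair; ``motifs`` the planted motif models (family "activity"
    motifs shift activity in both environments, family "trans" motifs shift it
    in mESC only); ``placements`` which pairs carry which motif and in which
    member; ``barcode_map`` the library's barcode assignments.
    """

    alpha: pd.DataFrame
    pairs: pd.DataFrame
    motifs: pd.DataFrame
    placements: pd.DataFrame
    barcode_map: pd.DataFrame
    pwms: dict[str, np.ndarray] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha.reset_index().to_dict(orient="list"),
            "pairs": self.pairs.to_dict(orient="list"),
            "motifs": self.motifs.to_dict(orient="list"),
            "placements": self.placements.to_dict(orient="list"),
            "pwms": {k: v.tolist() for k, v in self.pwms.items()},
        }
        Path(path).write_text(json.dumps(payload))


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # independent stream per stage, all derived from the single config seed
    return np.random.default_rng([stage, config.seed])


def simulate_truth(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the element catalog and all planted parameters.

    Returns
    -------
    catalog : DataFrame with one row per element
        columns: element_id, pair_id, species, biotype, conserved, tile, class.
    truth : GroundTruth
    """
    rng = _stage_rng(config, 0)
    n = config.n_pairs

    pair_ids = [f"pair{i:05d}" for i in range(n)]
    props = [config.biotype_proportions.get(b, 0.0) for b in BIOTYPES]
    biotypes = rng.choice(BIOTYPES, size=n, p=np.asarray(props) / np.sum(props))
    conserved = rng.random(n) < config.frac_conserved

    # planted motif models; trans motifs are always pair-symmetric so that the
    # cis truth is environment-independent
    motif_ids = [f"M{j:03d}" for j in range(config.n_motifs)]
    families = np.array(
        ["activity" if j % 2 == 0 else "trans" for j in range(config.n_motifs)]
    )
    betas = rng.normal(0.0, config.motif_effect_sd, size=config.n_motifs)
    consensus = [
        "".join(_BASES[rng.integers(0, 4, size=MOTIF_WIDTH)]) for _ in motif_ids
    ]
    motifs = pd.DataFrame(
        {
            "motif_id": motif_ids,
            "tf": [f"TF_{m}" for m in motif_ids],
            "family": families,
            "beta": betas,
            "consensus": consensus,
        }
    )
    pwms = {m: _consensus_pwm(c) for m, c in zip(motif_ids, consensus)}

    base = rng.normal(1.5, 0.8, size=n)
    has_cis = rng.random(n) < config.frac_cis
    has_trans = rng.random(n) < config.frac_trans
    cis_sign = rng.choice([-1.0, 1.0], size=n)
    trans_sign = rng.choice([-1.0, 1.0], size=n)
    # sign-couple co-occurring effects: compensatory = opposite signs
    both = has_cis & has_trans
    comp = both & (rng.random(n) < config.frac_compensatory)
    directional = both & ~comp
    trans_sign = np.where(comp, -cis_sign, trans_sign)
    trans_sign = np.where(directional, cis_sign, trans_sign)
    cis_mag = MIN_PLANTED_EFFECT + np.abs(
        rng.normal(0.0, config.cis_effect_sd, size=n)
    )
    trans_mag = MIN_PLANTED_EFFECT + np.abs(
        rng.normal(0.0, config.trans_effect_sd, size=n)
    )
    cis_shift = np.where(has_cis, cis_sign * cis_mag, 0.0)
    trans_shift = np.where(has_trans, trans_sign * trans_mag, 0.0)

    # activity motifs shift activity wherever present; they are placed
    # pair-symmetrically except in cis-effect pairs, where disruption (loss in
    # one member) contributes to the sequence-driven divergence
    act = families == "activity"
    trans_fam = families == "trans"
    placed = rng.random((n, config.n_motifs)) < MOTIF_PLACEMENT_PROB
    placed[:, trans_fam] = False
    disrupted = placed & (rng.random((n, config.n_motifs)) < MOTIF_DISRUPTION_PROB)
    disrupted &= has_cis[:, None]
    lost_in_human = rng.random((n, config.n_motifs)) < 0.5  # which member loses it

    # trans motifs carry no activity of their own here: they are planted
    # preferentially in trans-effect pairs whose shift matches the motif's
    # direction, always in both members, giving a recoverable association
    for j in np.nonzero(trans_fam)[0]:
        prob = np.where(
            has_trans & (trans_sign == np.sign(betas[j])),
            TRANS_MOTIF_MATCHED_PROB,
            TRANS_MOTIF_BACKGROUND_PROB,
        )
        placed[:, j] = rng.random(n) < prob
        disrupted[:, j] = False

    in_human = placed & ~(disrupted & lost_in_human)
    in_mouse = placed & ~(disrupted & ~lost_in_human)
    contrib_h = in_human[:, act] @ betas[act]
    contrib_m = in_mouse[:, act] @ betas[act]

    alpha_h_hesc = base + contrib_h
    alpha_m_hesc = base + contrib_m + cis_shift
    alpha_h_mesc = alpha_h_hesc + trans_shift
    alpha_m_mesc = alpha_m_hesc + trans_shift

    records = []
    alphas = {}
    for i, pid in enumerate(pair_ids):
        for sp, a_h, a_m in (
            ("human", alpha_h_hesc[i], alpha_h_mesc[i]),
            ("mouse", alpha_m_hesc[i], alpha_m_mesc[i]),
        ):
            eid = f"{pid}_{sp}"
            records.append(
                dict(
                    element_id=eid,
                    pair_id=pid,
                    species=sp,
                    biotype=biotypes[i],
                    conserved=bool(conserved[i]),
                    tile="tile1",
                    **{"class": "TSS"},
                )
            )
            alphas[eid] = (a_h, a_m)

    tss_min = min(min(v) for v in alphas.values()) if alphas else 0.0
    for k in range(config.n_negative_controls):
        eid = f"neg{k:05d}"
        records.append(
            dict(
                element_id=eid,
                pair_id="",
                species="",
                biotype="control",
                conserved=False,
                tile="",
                **{"class": "negative"},
            )
        )
        alphas[eid] = (tss_min, tss_min)
    for k in range(config.n_positive_controls):
        eid = f"pos{k:05d}"
        records.append(
            dict(
                element_id=eid,
                pair_id="",
                species="",
                biotype="control",
                conserved=False,
                tile="",
                **{"class": "positive"},
            )
        )
        alphas[eid] = (POSITIVE_CONTROL_ALPHA, POSITIVE_CONTROL_ALPHA)

    catalog = pd.DataFrame(records)
    alpha = pd.DataFrame(
        {
            "hESC": [alphas[e][0] for e in catalog["element_id"]],
            "mESC": [alphas[e][1] for e in catalog["element_id"]],
        },
        index=pd.Index(catalog["element_id"], name="element_id"),
    )

    cis_true = alpha_m_hesc - alpha_h_hesc
    trans_true = alpha_h_mesc - alpha_h_hesc
    # classify co-occurring pairs from the realized effect signs (motif
    # disruption can shift the realized cis effect past the explicit part)
    comp_true = both & (np.sign(cis_true) * np.sign(trans_true) < 0)
    dir_true = both & (np.sign(cis_true) * np.sign(trans_true) > 0)
    pairs = pd.DataFrame(
        {
            "pair_id": pair_ids,
            "biotype": biotypes,
            "conserved": conserved,
            "cis_true": cis_true,
            "trans_true": trans_true,
            "native_true": alpha_m_mesc - alpha_h_hesc,
            "has_cis": has_cis,
            "has_trans": has_trans,
            "compensatory_true": comp_true,
            "directional_true": dir_true,
        }
    )

    placements = pd.DataFrame(
        {
            "pair_id": np.repeat(pair_ids, config.n_motifs),
            "motif_id": np.tile(motif_ids, n),
            "in_human": in_human.ravel(),
            "in_mouse": in_mouse.ravel(),
        }
    )
    placements = placements[placements.in_human | placements.in_mouse].reset_index(
        drop=True
    )

    assignments = assign_barcodes(
        [(r["element_id"], r["class"]) for r in records],
        config.barcodes_per_class,
        seed=int(rng.integers(0, 2**31)),
    )
    barcode_map = pd.DataFrame(
        [
            {"barcode_id": bc, "element_id": eid}
            for eid, bcs in assignments.items()
            for bc in bcs
        ]
    )

    truth = GroundTruth(
        alpha=alpha,
        pairs=pairs,
        motifs=motifs,
        placements=placements,
        barcode_map=barcode_map,
        pwms=pwms,
    )
    return catalog, truth


def _consensus_pwm(consensus: str, p_match: float = 0.97) -> np.ndarray:
    pwm = np.full((len(consensus), 4), (1.0 - p_match) / 3.0)
    for i, b in enumerate(consensus):
        pwm[i, "ACGT".index(b)] = p_match
    return pwm


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_counts(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw barcode-level DNA and RNA count tables.

    One pooled input DNA library is sequenced; each environment is assayed in
    ``n_replicates`` RNA replicates.  A barcode's latent abundance ``w`` is
    gamma-distributed; its DNA count is NB around ``dna_depth``-scaled ``w``.
    RNA is transcribed from the DNA that actually made it into the pool, so a
    barcode's RNA mean is proportional to its realized DNA count times
    ``2**alpha*`` of its element in that environment, rescaled so every
    sample's expected total equals the configured depth.
    """
    rng = _stage_rng(config, 1)
    bm = truth.barcode_map
    n_bc = len(bm)
    weights = rng.gamma(4.0, 0.25, size=n_bc)

    dna_mean = config.dna_depth * weights / weights.sum()
    dna_counts = _nb_draw(rng, dna_mean, config.nb_dispersion)
    dna = pd.DataFrame(
        {
            "barcode_id": bm["barcode_id"],
            "element_id": bm["element_id"],
            "count": dna_counts,
        }
    )

    alpha = truth.alpha
    rna_rows = []
    for env in ENVIRONMENTS:
        signal = dna_counts * np.power(
            2.0, alpha.loc[bm["element_id"], env].to_numpy()
        )
        mean = config.rna_depth * signal / signal.sum()
        for rep in range(1, config.n_replicates + 1):
            rna_rows.append(
                pd.DataFrame(
                    {
                        "barcode_id": bm["barcode_id"],
                        "element_id": bm["element_id"],
                        "environment": env,
                        "replicate": rep,
                        "count": _nb_draw(rng, mean, config.nb_dispersion),
                    }
                )
            )
    rna = pd.concat(rna_rows, ignore_index=True)
    return dna, rna


def simulate_sequences(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Emit 144-bp regulatory sequences with planted exact-consensus motifs.

    Pair members are mutated copies of a common ancestor (10% of positions
    resampled) so orthologs are similar but not identical; GC composition
    varies between pairs by construction.  Motifs are written at the same
    offset in both members; a disrupted motif is written in only one member
    and the other member keeps its background sequence at that offset.
    """
    rng = _stage_rng(config, 2)
    widths = {m: len(c) for m, c in zip(truth.motifs.motif_id, truth.motifs.consensus)}
    if widths and max(widths.values()) > TILE_LENGTH:
        raise ConfigurationError("motif longer than the 144-bp tile")

    consensus = dict(zip(truth.motifs.motif_id, truth.motifs.consensus))
    n_slots = TILE_LENGTH // MOTIF_WIDTH
    by_pair = dict(tuple(truth.placements.groupby("pair_id")))

    rows = []
    pair_ids = truth.pairs["pair_id"].tolist()
    for pid in pair_ids:
        gc = rng.uniform(0.30, 0.70)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        ancestor = rng.choice(4, size=TILE_LENGTH, p=p)
        seqs = {}
        for sp in SPECIES:
            s = ancestor.copy()
            mut = rng.random(TILE_LENGTH) < 0.10
            s[mut] = rng.choice(4, size=int(mut.sum()), p=p)
            seqs[sp] = s
        placed = by_pair.get(pid)
        if placed is not None:
            slots = rng.choice(n_slots, size=len(placed), replace=False)
            for (_, row), slot in zip(placed.iterrows(), slots):
                offset = int(slot) * MOTIF_WIDTH
                word = np.array(["ACGT".index(b) for b in consensus[row.motif_id]])
                if row.in_human:
                    seqs["human"][offset : offset + len(word)] = word
                if row.in_mouse:
                    seqs["mouse"][offset : offset + len(word)] = word
        for sp in SPECIES:
            rows.append(
                {
                    "element_id": f"{pid}_{sp}",
                    "sequence": "".join(_BASES[seqs[sp]]),
                }
            )
    return pd.DataFrame(rows)


def simulate_cage_context(
    config: SimulationConfig,
    catalog: pd.DataFrame | None = None,
    redundant_per_element: int | None = None,
) -> dict:
    """Generate the expression-context inputs for redundancy analysis.

    Returns a dict with

    * ``expression``: log-scale-friendly expression matrix (rows: focal
      elements then enhancers; columns: samples).  Values are ``expm1`` of a
      latent Gaussian so that the downstream ``log1p`` transform recovers the
      latent correlations exactly.
    * ``tads``: TAD intervals (chrom, start, end, source) for both sources.
    * ``positions``: genomic positions of focal elements and enhancers.
    * ``truth``: per-element set of planted redundant enhancer ids.

    The TF differential-expression table is produced separately by
    :func:`simulate_tf_de_table`, which needs the planted motif directions.
    """
    rng = _stage_rng(config, 3)
    tad_size = 100_000
    tads = pd.DataFrame(
        [
            {
                "chrom": "chrT",
                "start": i * tad_size,
                "end": (i + 1) * tad_size,
                "source": src,
            }
            for src in ("hESC", "mESC")
            for i in range(config.n_tads)
        ]
    )

    if catalog is not None:
        focal_ids = list(
            catalog.loc[catalog["class"] == "TSS", "element_id"]
        )
    else:
        focal_ids = [f"elem{i:04d}" for i in range(config.n_tads)]
    n_red = (
        redundant_per_element
        if redundant_per_element is not None
        else config.enhancers_per_tad // 2
    )
    if n_red > config.enhancers_per_tad:
        raise ConfigurationError("more redundant enhancers than enhancers per TAD")

    n_samp = config.n_expression_samples
    rho = config.redundancy_correlation
    positions = []
    expr_rows = {}
    red_truth: dict[str, list[str]] = {}

    # place one enhancer ensemble per TAD; focal elements round-robin over TADs
    enh_latent: dict[str, np.ndarray] = {}
    for i, eid in enumerate(focal_ids):
        tad = i % config.n_tads
        pos = tad * tad_size + int(rng.integers(1000, tad_size - 1000))
        positions.append({"id": eid, "chrom": "chrT", "position": pos, "kind": "element"})
        focal = rng.standard_normal(n_samp)
        expr_rows[eid] = focal
        red_truth[eid] = []
        if i < config.n_tads:  # one ensemble per TAD, tied to its first element
            for k in range(config.enhancers_per_tad):
                enh_id = f"enh_t{tad:03d}_{k:02d}"
                pos_e = tad * tad_size + int(rng.integers(1000, tad_size - 1000))
                positions.append(
                    {"id": enh_id, "chrom": "chrT", "position": pos_e, "kind": "enhancer"}
                )
                if k < n_red:
                    z = rho * focal + np.sqrt(1 - rho**2) * rng.standard_normal(n_samp)
                else:
                    z = rng.standard_normal(n_samp)
                enh_latent[enh_id] = z
        for k in range(n_red):
            red_truth[eid].append(f"enh_t{tad:03d}_{k:02d}")

    latent = pd.DataFrame(
        {**expr_rows, **enh_latent},
        index=pd.RangeIndex(n_samp),
    ).T
    latent.columns = [f"sample{j:04d}" for j in range(n_samp)]
    expression = np.expm1(np.clip(latent * 1.0 + 5.0, 0.0, None))

    return {
        "expression": pd.DataFrame(
            expression, index=latent.index, columns=latent.columns
        ),
        "tads": tads,
        "positions": pd.DataFrame(positions),
        "truth": red_truth,
    }


def simulate_conservation_inputs(
    catalog: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mapping table and CAGE coverage track consistent with catalog labels.

    Each TSS element gets a reciprocally mapped position on a toy chromosome;
    the per-position maximum-CAGE-coverage track carries >= 10 reads inside
    the ±50 bp window of conserved elements and < 10 for non-conserved ones.
    Orthology mapping itself (liftOver) is out of scope; this emits the
    finished mapping table that module consumes.
    """
    rng = _stage_rng(config, 5)
    tss = catalog[catalog["class"] == "TSS"].reset_index(drop=True)
    spacing = 1000
    mapping_rows, coverage_rows = [], []
    for i, r in tss.iterrows():
        pos = 500 + i * spacing
        mapping_rows.append(
            dict(
                element_id=r["element_id"],
                chromosome="chrMap",
                mapped_position=pos,
                reciprocal_ok=True,
            )
        )
        peak = int(rng.integers(10, 40)) if r["conserved"] else int(rng.integers(0, 10))
        offset = int(rng.integers(-50, 51))
        coverage_rows.append(
            dict(chromosome="chrMap", position=pos + offset, value=peak)
        )
    return pd.DataFrame(mapping_rows), pd.DataFrame(coverage_rows)


def simulate_tf_de_table(
    truth: GroundTruth, config: SimulationConfig, frac_matched: float = 1.0
) -> pd.DataFrame:
    """TF differential-expression table (mESC vs hESC log2 fold changes).

    Every planted trans motif's TF receives a strong fold change whose sign
    matches its planted trans direction (for a ``frac_matched`` subset);
    activity-motif TFs receive sub-threshold fold changes, plus a handful of
    unrelated non-differential genes.
    """
    rng = _stage_rng(config, 4)
    rows = []
    for _, m in truth.motifs.iterrows():
        if m.family == "trans" and rng.random() < frac_matched:
            lfc = np.sign(m.beta) * (1.5 + abs(rng.normal(0, 0.5)))
            q = 10.0 ** rng.uniform(-8, -3)
        else:
            lfc = rng.normal(0.0, 0.3)
            q = rng.uniform(0.2, 1.0)
        rows.append({"gene": m.tf, "log2fc_mESC_vs_hESC": lfc, "qvalue": q})
    for j in range(20):
        rows.append(
            {
                "gene": f"GENE_{j:03d}",
                "log2fc_mESC_vs_hESC": rng.normal(0.0, 0.3),
                "qvalue": rng.uniform(0.2, 1.0),
            }
        )
    return pd.DataFrame(rows)
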