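"""End-to-end orchestration: simulate -> quantify -> differential ->
compensation -> motifs -> redundancy -> conservation -> report.

Each stage consumes the previous stage's tables and the single global seed is
fanned out into per-stage derived streams, so a rerun with the same config
reproduces every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

import cistrans
from cistrans import activity as act
from cistrans import compensation as comp
from cistrans import differential as diff
from cistrans import io as cio
from cistrans import motifs as mot
from cistrans import redundancy as red
from cistrans import simulate as sim
from cistrans.config import SimulationConfig
from cistrans.conservation import CoverageTrack, classify_table

logger = logging.getLogger("cistrans")


def run_pipeline(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    n_null_pairs_per_tile: int = 50,
    with_motifs: bool = True,
    with_redundancy: bool = True,
    with_conservation: bool = True,
) -> dict:
    """Run the full synthetic analysis and return the machine-readable report.

    When ``outdir`` is given every intermediate table is written there as
    TSV/FASTA/BED/JSON.
    """
    report: dict = {"provenance": _provenance(config)}
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    catalog, truth = sim.simulate_truth(config)
    dna, rna = sim.simulate_counts(truth, config)
    logger.info("simulated %d elements, %d barcodes", len(catalog), len(dna))
    if out is not None:
        cio.write_tsv(catalog, out / "catalog.tsv")
        cio.write_tsv(truth.barcode_map, out / "barcode_map.tsv")
        cio.write_tsv(dna, out / "dna_counts.tsv")
        cio.write_tsv(rna, out / "rna_counts.tsv")
        truth.to_json(out / "truth.json")

    # --- quantify ---------------------------------------------------------
    kept = act.filter_by_dna_representation(dna, truth.barcode_map)
    logger.info("DNA filter: kept %d / %d elements", len(kept), len(catalog))
    obs = act.compute_log_ratios(dna, rna, kept)
    activities = act.estimate_activity(obs)
    negatives = set(catalog.loc[catalog["class"] == "negative", "element_id"])
    tested = act.test_active(activities, negatives)
    report["quantify"] = {
        "n_elements_kept": len(kept),
        "n_elements_dropped": len(catalog) - len(kept),
        "n_active": int(tested["active"].sum()),
        "n_tested": len(tested),
    }
    if out is not None:
        cio.write_tsv(tested, out / "activity.tsv")

    # --- active-pair filter ----------------------------------------------
    tss = catalog[catalog["class"] == "TSS"]
    native_env = {"human": "hESC", "mouse": "mESC"}
    active_native = set(
        tested.loc[tested["active"], ["element_id", "environment"]]
        .itertuples(index=False, name=None)
    )
    active_pairs = {
        pid
        for pid, grp in tss.groupby("pair_id")
        if any(
            (r.element_id, native_env[r.species]) in active_native
            for r in grp.itertuples()
        )
    }
    report["active_pairs"] = {
        "n_pairs": tss["pair_id"].nunique(),
        "n_active_pairs": len(active_pairs),
        "fraction_active": len(active_pairs) / max(tss["pair_id"].nunique(), 1),
    }

    # --- differential -----------------------------------------------------
    positives = sorted(catalog.loc[catalog["class"] == "positive", "element_id"])
    null_seed = int(np.random.default_rng([10, config.seed]).integers(0, 2**31))
    nulls = diff.build_null_pairs(
        truth.barcode_map, positives, n_null_pairs_per_tile, seed=null_seed
    )
    results = diff.run_effect_scans(obs, catalog, nulls, active_pairs)
    calibration = diff.calibrate_empirical_fdr(results)
    results = diff.apply_significance(results, calibration)
    assigned = diff.assign_effects(results)
    real = assigned[~assigned["is_null"]]

    report["calibration"] = {
        fam: {
            "q_cutoff": c.q_cutoff,
            "effect_floor": c.effect_floor,
            "achieved_null_rate": c.achieved_null_rate,
        }
        for fam, c in calibration.items()
    }
    report["differential"] = {
        axis: {
            "n_tested": int(m.sum()),
            "fraction_significant": float(
                results.loc[m, "significant"].mean()
            ) if m.any() else np.nan,
        }
        for axis in diff.AXES
        for m in [(results["axis"] == axis) & ~results["is_null"] & results["p"].notna()]
    }
    report["differential"]["fraction_pairs_cis"] = float(real["cis_sig"].mean())
    report["differential"]["fraction_pairs_trans"] = float(real["trans_sig"].mean())
    if out is not None:
        cio.write_tsv(results, out / "effects.tsv")
        cio.write_tsv(assigned.reset_index(), out / "assigned_effects.tsv")
        cio.write_json(report["calibration"], out / "calibration.json")

    # --- compensation -----------------------------------------------------
    odds, fisher_p = comp.cooccurrence_test(
        real.rename(columns={"cis_sig": "cis_sig", "trans_sig": "trans_sig"})
    )
    calls, fractions = comp.classify_pairs(real, truth.pairs)
    report["compensation"] = {
        "odds_ratio": odds,
        "fisher_p": fisher_p,
        "n_both": int((real["cis_sig"] & real["trans_sig"]).sum()),
        "fractions_by_group": fractions.to_dict(orient="records"),
    }
    class_of_pair = calls.set_index("pair_id")["class"] if not calls.empty else pd.Series(dtype=object)
    try:
        native_cmp = comp.compare_native_by_class(
            real["native_effect"], class_of_pair.reindex(real.index)
        )
        report["compensation"]["native_by_class"] = native_cmp
    except ValueError as err:
        report["compensation"]["native_by_class"] = {"skipped": str(err)}
    if out is not None and not calls.empty:
        cio.write_tsv(calls, out / "compensation.tsv")

    # --- motifs -----------------------------------------------------------
    if with_motifs:
        report["motifs"] = _motif_stage(config, catalog, truth, tested, real, results, out)

    # --- redundancy -------------------------------------------------------
    if with_redundancy:
        report["redundancy"] = _redundancy_stage(
            config, catalog, class_of_pair, out
        )

    # --- conservation -----------------------------------------------------
    if with_conservation:
        mapping, coverage = sim.simulate_conservation_inputs(catalog, config)
        span_hi = max(
            int(coverage["position"].max()), int(mapping["mapped_position"].max())
        )
        span = (0, span_hi + 60)
        track = CoverageTrack(
            dict(zip(coverage["position"], coverage["value"])), span=span
        )
        cons = classify_table(mapping, {"chrMap": track})
        merged = cons.merge(
            catalog[["element_id", "conserved"]], on="element_id"
        )
        agreement = float(
            (
                (merged["conservation"] == "conserved") == merged["conserved"]
            ).mean()
        )
        report["conservation"] = {
            "n_classified": len(cons),
            "n_conserved": int((cons["conservation"] == "conserved").sum()),
            "agreement_with_truth": agreement,
        }
        if out is not None:
            cio.write_tsv(cons, out / "conservation.tsv")

    _check_fractions(report)
    if out is not None:
        cio.write_json(report, out / "report.json")
    return report


def _motif_stage(config, catalog, truth, tested, real, results, out) -> dict:
    sequences = sim.simulate_sequences(truth, config)
    comps = pd.DataFrame(
        [
            {
                "element_id": r.element_id,
                "gc_content": mot.sequence_composition(r.sequence).gc_content,
                "cpg_rate": mot.sequence_composition(r.sequence).cpg_rate,
            }
            for r in sequences.itertuples()
        ]
    ).set_index("element_id")
    presence = mot.build_presence_matrix(sequences, truth.pwms)

    mean_activity = tested.groupby("element_id")["alpha"].mean()
    idx = presence.index.intersection(mean_activity.index)
    activity_res = mot.fit_model_family(
        "activity",
        presence.loc[idx],
        mean_activity.loc[idx],
        comps.loc[idx],
        min_per_group=min(20, max(5, len(idx) // 20)),
    )

    indicators = mot.pair_motif_indicators(presence, catalog)
    disrupted = (
        indicators.assign(
            disrupted=indicators["disrupted_in_human"] | indicators["disrupted_in_mouse"]
        )
        .pivot(index="pair_id", columns="motif_id", values="disrupted")
        .fillna(False)
    )
    tss = catalog[catalog["class"] == "TSS"]
    pair_comp_rows = []
    for pid, grp in tss.groupby("pair_id"):
        by_sp = dict(zip(grp["species"], grp["element_id"]))
        if not {"human", "mouse"} <= set(by_sp):
            continue
        ch, cm = comps.loc[by_sp["human"]], comps.loc[by_sp["mouse"]]
        pair_comp_rows.append(
            dict(
                pair_id=pid,
                mean_gc=(ch.gc_content + cm.gc_content) / 2,
                mean_cpg=(ch.cpg_rate + cm.cpg_rate) / 2,
                abs_dgc=abs(ch.gc_content - cm.gc_content),
                abs_dcpg=abs(ch.cpg_rate - cm.cpg_rate),
            )
        )
    pair_comps = pd.DataFrame(pair_comp_rows).set_index("pair_id")
    cis_idx = disrupted.index.intersection(real.index)
    cis_res = mot.fit_model_family(
        "cis",
        disrupted.loc[cis_idx],
        real["cis_effect"].abs().loc[cis_idx],
        pair_comps.loc[cis_idx],
    )

    # per-sequence trans effects from the sequence's own axis model
    trans_eff = {}
    for r in results[
        results["axis"].isin(["trans_human_seq", "trans_mouse_seq"]) & ~results["is_null"]
    ].itertuples():
        sp = "human" if r.axis == "trans_human_seq" else "mouse"
        trans_eff[f"{r.unit_id}_{sp}"] = r.effect
    trans_series = pd.Series(trans_eff)
    t_idx = presence.index.intersection(trans_series.index)
    trans_res = mot.fit_model_family(
        "trans", presence.loc[t_idx], trans_series.loc[t_idx], comps.loc[t_idx]
    )

    shared = None
    try:
        shared = mot.shared_fraction_comparison(presence, catalog, real["cis_sig"])
    except ValueError as err:
        shared = {"skipped": str(err)}
    biotypes = catalog.set_index("element_id").loc[presence.index, "biotype"]
    enrich = mot.biotype_enrichment(presence, biotypes)
    tf_de = sim.simulate_tf_de_table(truth, config)
    agree = mot.direction_agreement(
        trans_res if not trans_res.empty else pd.DataFrame(columns=["motif_id", "beta", "significant"]),
        tf_de,
        truth.motifs,
    )

    if out is not None:
        cio.write_fasta(sequences, out / "sequences.fasta")
        cio.write_meme(truth.pwms, out / "motifs.meme")
        cio.write_tsv(tf_de, out / "tf_de.tsv")
        for name, df in (
            ("motif_activity", activity_res),
            ("motif_cis", cis_res),
            ("motif_trans", trans_res),
            ("motif_biotype_enrichment", enrich),
        ):
            if not df.empty:
                cio.write_tsv(df, out / f"{name}.tsv")

    summarise = lambda df: {
        "n_fit": len(df),
        "n_significant": int(df["significant"].sum()) if not df.empty else 0,
    }
    return {
        "n_motifs": len(truth.pwms),
        "n_elements_with_hits": int(presence.any(axis=1).sum()),
        "activity_family": summarise(activity_res),
        "cis_family": summarise(cis_res),
        "trans_family": summarise(trans_res),
        "shared_motifs": shared,
        "n_biotype_enrichments": summarise(enrich),
        "direction_agreement": {
            k: v for k, v in agree.items() if k != "table"
        },
    }


def _redundancy_stage(config, catalog, class_of_pair, out) -> dict:
    context = sim.simulate_cage_context(config, catalog)
    positions = context["positions"]
    elem_pos = positions[positions["kind"] == "element"].rename(columns={"id": "id"})
    enh_pos = positions[positions["kind"] == "enhancer"]
    table = red.redundancy_table(
        elem_pos, enh_pos, context["tads"], context["expression"]
    )
    pair_of = dict(
        zip(catalog["element_id"], catalog["pair_id"])
    )
    classes = pd.Series(
        {
            eid: class_of_pair.get(pair_of.get(eid, ""), "neither")
            for eid in table["element_id"]
        }
    )
    tad_size = 100_000
    tad_of = {
        r["id"]: int(r["position"]) // tad_size for _, r in elem_pos.iterrows()
    }
    try:
        robustness = red.dedupe_downsample(
            table, tad_of, classes, n_resamples=20, seed=config.seed
        )
    except ValueError as err:
        robustness = {"skipped": str(err)}
    if out is not None:
        cio.write_tsv(table, out / "redundancy.tsv")
        cio.write_bed(context["tads"], out / "tads.bed")
        cio.write_tsv(
            context["expression"].reset_index(names="id"), out / "expression.tsv"
        )
    return {
        "n_elements": len(table),
        "mean_tad_enhancers": float(table["n_tad_enhancers"].mean()),
        "mean_redundant": float(table["n_redundant"].mean()),
        "downsample_robustness": robustness,
    }


def _provenance(config: SimulationConfig) -> dict:
    cfg = config.to_dict()
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    return {"config": cfg, "config_hash": digest, "seed": config.seed,
            "version": cistrans.__version__}


def _check_fractions(report: dict) -> None:
    # every reported fraction must be a probability
    def walk(node):
        if isinstance(node, dict):
            for k, v in node.items():
                if isinstance(v, (int, float)) and str(k).startswith(("frac", "fraction")):
                    if not (np.isnan(v) or 0.0 <= v <= 1.0):
                        raise AssertionError(f"fraction out of range: {k}={v}")
                else:
                    walk(v)
        elif isinstance(node, list):
            for v in node:
                walk(v)

    walk(report)
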