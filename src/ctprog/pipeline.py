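"""End-to-end orchestration: simulate -> preprocess -> train -> fuse -> evaluate.

The cohort is split by synthetic recruiting center (or per patient) into
training, validation and test sets; the clinical Cox model and the fusion
coefficients are fitted on the training split only, and the stratification
cutoff is always the training-set median score, frozen before it is applied to
the held-out splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ctprog import clinical as clin_mod
from ctprog import evalstats
from ctprog.phantom import (ClinicalRecord, PatientVolumeSet, PhantomConfig,
                            generate_cohort, records_to_frame, size_based_progression)
from ctprog.preprocess import assemble_pack
from ctprog.survnet.model import NetConfig, RiskModel, train


@dataclass(frozen=True)
class SplitSpec:
    """How to partition the cohort.

    ``unit`` is "patient" or "center"; fractions (train, val, test) must be
    positive and sum to 1. Unit counts are allocated as floor(frac * n) for the
    training and validation sets, with the remainder going to the test set.
    """

    unit: str = "center"
    fractions: tuple[float, float, float] = (0.64, 0.16, 0.20)
    seed: int = 0

    def __post_init__(self):
        if self.unit not in ("patient", "center"):
            raise ValueError("unit must be 'patient' or 'center'")
        if any(f <= 0 for f in self.fractions) or not np.isclose(sum(self.fractions), 1.0):
            raise ValueError("fractions must be positive and sum to 1")


def split_cohort(records: Sequence[ClinicalRecord],
                 spec: SplitSpec) -> tuple[set[str], set[str], set[str]]:
    """Seeded, disjoint and exhaustive train/val/test split of patient ids."""
    if spec.unit == "center":
        units: dict = {}
        for r in records:
            units.setdefault(r.center, []).append(r.patient_id)
    else:
        units = {r.patient_id: [r.patient_id] for r in records}
    if len(units) < 3:
        raise ValueError("need at least 3 units to form three splits")
    keys = sorted(units)
    rng = np.random.default_rng(spec.seed)
    rng.shuffle(keys)
    n = len(keys)
    n_train = int(np.floor(spec.fractions[0] * n))
    n_val = int(np.floor(spec.fractions[1] * n))
    n_train = max(1, n_train)
    n_val = max(1, n_val)
    train_u = keys[:n_train]
    val_u = keys[n_train:n_train + n_val]
    test_u = keys[n_train + n_val:]
    to_ids = lambda us: {pid for u in us for pid in units[u]}
    return to_ids(train_u), to_ids(val_u), to_ids(test_u)


def _subset(items, ids):
    return [x for x in items if x.patient_id in ids]


def run_pipeline(phantom_config: PhantomConfig, net_config: NetConfig,
                 split: SplitSpec | None = None,
                 horizons: Sequence[float] = (365.0, 730.0),
                 out_dir: str | Path | None = None) -> dict:
    """Execute every stage and return (and optionally write) the metrics bundle.

    Trains both the baseline-only (Rad-S) and spatial-temporal (Rad-D) imaging
    models, the clinical Cox model, and both fusion models, then reports
    C-index, time-dependent AUC at the requested horizons, and HR/log-rank
    stratification (training-median cutoff) for all five variants on each split.
    """
    split = split or SplitSpec(seed=phantom_config.seed)
    vol_sets, records, true_lp = generate_cohort(phantom_config)
    packs = [assemble_pack(v) for v in vol_sets]
    train_ids, val_ids, test_ids = split_cohort(records, split)

    by_id = {r.patient_id: r for r in records}
    splits = {"train": train_ids, "validation": val_ids, "test": test_ids}

    # imaging models (trained on the training split only)
    score_tables: dict[str, pd.DataFrame] = {}
    train_packs = _subset(packs, train_ids)
    train_records = _subset(records, train_ids)
    models: dict[str, RiskModel] = {}
    for variant in ("rad_s", "rad_d"):
        cfg = replace(net_config, variant=variant)
        model, _ = train(train_packs, train_records, cfg)
        models[variant] = model
        scored = model.score_packs(packs)
        score_tables[variant] = pd.DataFrame(
            {"patient_id": [s.patient_id for s in scored],
             "score": [s.score for s in scored], "variant": variant})

    # clinical model
    cohort_df = records_to_frame(records).set_index("patient_id")
    train_df = cohort_df.loc[sorted(train_ids)]
    # lightly ridge-stabilized: at desk-scale training splits a rare covariate
    # (e.g. external-beam radiotherapy at 5% prevalence) can separate
    cln_fit = clin_mod.fit_cox(
        train_df[list(clin_mod.PUBLISHED_CLINICAL_COEFFS)],
        train_df.os_days.to_numpy(), train_df.event.to_numpy(), ridge=0.1)
    score_tables["cln"] = clin_mod.clinical_scores(records, cln_fit)

    # fusion models (coefficients fitted on the training split, then frozen)
    fusion_fits = {}
    for variant, fused in (("rad_s", "radcln_s"), ("rad_d", "radcln_d")):
        rad_train = score_tables[variant][score_tables[variant].patient_id.isin(train_ids)]
        cln_train = score_tables["cln"][score_tables["cln"].patient_id.isin(train_ids)]
        ffit = clin_mod.fit_fusion(rad_train, cln_train, train_records, ridge=0.1)
        fusion_fits[fused] = ffit
        score_tables[fused] = clin_mod.fuse_frames(score_tables[variant],
                                                   score_tables["cln"], ffit)

    # evaluation: cutoff = training-split median of each variant's scores
    results: dict = {"seeds": {"phantom": phantom_config.seed,
                               "net": net_config.seed, "split": split.seed},
                     "n_patients": len(records), "variants": {}}
    for variant, table in score_tables.items():
        table = table.set_index("patient_id")
        cutoff = float(table.loc[sorted(train_ids), "score"].median())
        variant_res = {"cutoff": cutoff, "splits": {}}
        for split_name, ids in splits.items():
            sel = sorted(ids)
            sc = table.loc[sel, "score"].to_numpy()
            t = np.array([by_id[p].os_days for p in sel])
            e = np.array([by_id[p].event for p in sel])
            try:
                ev = evalstats.evaluate_scores(sc, t, e, list(horizons), cutoff)
                variant_res["splits"][split_name] = {
                    "c_index": ev.c_index,
                    "c_index_ci": list(ev.c_index_ci),
                    "auc_t": {str(h): ev.auc_t[h] for h in ev.auc_t},
                    "hr": ev.hr, "hr_ci": list(ev.hr_ci),
                    "logrank_p": ev.logrank_p,
                    "n": len(sel),
                }
            except ValueError as exc:
                variant_res["splits"][split_name] = {"error": str(exc), "n": len(sel)}
        results["variants"][variant] = variant_res

    # size-based comparator on the whole cohort, against the fused deep model
    prog = np.array([size_based_progression(v) for v in vol_sets])
    fused_table = score_tables["radcln_d"].set_index("patient_id")
    all_ids = sorted(by_id)
    comp = evalstats.compare_stratifiers(
        fused_table.loc[all_ids, "score"].to_numpy(),
        float(fused_table.loc[sorted(train_ids), "score"].median()),
        prog,
        np.array([by_id[p].os_days for p in all_ids]),
        np.array([by_id[p].event for p in all_ids]))
    results["stratifier_comparison"] = comp

    # recovery diagnostics against the generative ground truth
    c_true, _, _ = evalstats.harrell_c(
        true_lp, [r.os_days for r in records], [r.event for r in records])
    results["ground_truth_c_index"] = c_true

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.json").write_text(json.dumps(results, indent=1, sort_keys=True))
        for variant, table in score_tables.items():
            table.reset_index(drop=True) if table.index.name else table
            score_tables[variant].to_csv(out / f"scores_{variant}.csv", index=False)
        for name, model in models.items():
            model.save(out / f"model_{name}.pkl")
    return results
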