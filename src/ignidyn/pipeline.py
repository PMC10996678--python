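"""End-to-end orchestration: per-subject ignition → cohort statistics →
mixed models → staging classifiers, with every output written as TSV/JSON
into a run directory.

All randomness flows from the config's master seed through named per-stage
substreams, so a rerun with the same inputs reproduces every output byte for
byte, and changing the seed perturbs only the Monte-Carlo stages.
"""

from __future__ import annotations

import itertools
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as iio
from .classify import build_feature_table, nested_cv
from .config import StudyConfig
from .errors import IgnidynError, ParameterError
from .ignition import run_ignition
from .lme import build_long_table, fit_rsn_lme, fit_wholebrain_lme, rsn_effect
from .rsn import RSN_NAMES, SUBCORT
from .stats import build_hierarchy, compare_groups, hdf

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "stage_rng"]

GROUP_ORDER = ("HC", "MCI", "AD")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream of the master seed."""
    h = np.random.SeedSequence([seed, zlib.crc32(stage.encode()) % 2**31])
    return np.random.default_rng(h)


def _fail(stage: str, subject: str | None, exc: Exception) -> IgnidynError:
    where = f"stage {stage!r}" + (f", subject {subject!r}" if subject else "")
    return IgnidynError(f"pipeline aborted at {where}: {exc}")


def run_pipeline(
    config: StudyConfig,
    manifest: pd.DataFrame,
    out_dir,
    labels: pd.Series | None = None,
    skip_bandpass: bool = False,
) -> Path:
    """Run every analysis stage over a cohort manifest.

    ``manifest`` has columns subject_id / diagnosis / timeseries_path (and
    optionally burden_path); ``labels`` maps region id to RSN (enables the
    RSN-level mixed model).  Returns the run directory, which afterwards
    contains ignition profiles, cohort hierarchies and disruption factors,
    group comparisons, mixed-model reports, classification reports and a
    JSON log of every parameter used.
    """
    if len(manifest) == 0:
        raise ParameterError("empty cohort manifest")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    profiles, groups = {}, {}
    band = None if skip_bandpass else (config.band_low_hz, config.band_high_hz)
    for rec in manifest.itertuples(index=False):
        try:
            series = iio.read_timeseries(
                rec.timeseries_path, tr_seconds=config.tr_seconds, subject_id=rec.subject_id
            )
            prof, _ = run_ignition(
                series, theta=config.threshold_theta, window_trs=config.window_trs, band=band
            )
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise _fail("ignition", rec.subject_id, exc) from exc
        profiles[rec.subject_id] = prof
        groups[rec.subject_id] = rec.diagnosis
    iio.write_profiles(out / "profiles.tsv", list(profiles.values()))

    by_group = {
        g: [profiles[s] for s in profiles if groups[s] == g]
        for g in GROUP_ORDER
        if any(groups[s] == g for s in profiles)
    }
    try:
        hierarchies = {g: build_hierarchy(p) for g, p in by_group.items()}
        for g, h in hierarchies.items():
            pd.DataFrame({"region_id": h.region_ids, "mean_metastability": h.values}).to_csv(
                out / f"hierarchy_{g}.tsv", sep="\t", index=False
            )
        hdf_rows = [
            {"a": a, "b": b, "hdf": hdf(hierarchies[a], hierarchies[b])}
            for a, b in itertools.combinations(hierarchies, 2)
        ]
        pd.DataFrame(hdf_rows).to_csv(out / "hdf.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise _fail("hierarchy", None, exc) from exc

    try:
        subject_means = {
            g: np.array(
                [np.nanmean(profiles[s].node_metastability) for s in profiles if groups[s] == g]
            )
            for g in by_group
        }
        comparable = {g: v for g, v in subject_means.items() if v.size >= 2}
        if len(comparable) >= 2:
            comparisons = compare_groups(
                comparable,
                n_perm=config.n_permutations,
                fdr_q=config.fdr_q,
                rng=stage_rng(config.seed, "group-compare"),
            )
            comparisons.to_csv(out / "group_comparisons.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise _fail("group-compare", None, exc) from exc

    have_burden = "burden_path" in manifest.columns and manifest["burden_path"].notna().all()
    if have_burden:
        ref_ids = list(next(iter(profiles.values())).region_ids)
        burdens = {}
        for rec in manifest.itertuples(index=False):
            try:
                burdens[rec.subject_id] = iio.read_burden_table(rec.burden_path, ref_ids)
            except Exception as exc:  # noqa: BLE001
                raise _fail("burden-io", rec.subject_id, exc) from exc
        try:
            if labels is None:
                labels = pd.Series("CNT", index=pd.Index(ref_ids, name="region_id"))
            table = build_long_table(list(profiles.values()), burdens, labels)
            wb = fit_wholebrain_lme(table)
            wb.fixed.rename_axis("term").reset_index().to_csv(
                out / "lme_wholebrain.tsv", sep="\t", index=False
            )
            if table[table["rsn"] != SUBCORT]["rsn"].nunique() >= 2:
                rs = fit_rsn_lme(table)
                rs.fixed.rename_axis("term").reset_index().to_csv(
                    out / "lme_rsn.tsv", sep="\t", index=False
                )
                rows = []
                for rsn in sorted(set(table["rsn"]) & set(RSN_NAMES)):
                    for eff in ("abeta", "tau", "interaction"):
                        est, se, p = rsn_effect(rs, eff, rsn)
                        rows.append({"rsn": rsn, "effect": eff, "estimate": est, "std_error": se, "p_value": p})
                pd.DataFrame(rows).to_csv(out / "lme_rsn_effects.tsv", sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise _fail("lme", None, exc) from exc

        try:
            feats = build_feature_table(profiles, burdens)
            feats = feats.dropna(axis=1)
            reports = []
            class_rng = stage_rng(config.seed, "classify")
            for ga, gb in itertools.combinations(by_group, 2):
                sids = [s for s in profiles if groups[s] in (ga, gb)]
                y = np.array([groups[s] == gb for s in sids], dtype=int)
                if min(y.sum(), len(y) - y.sum()) < 2:
                    continue
                rep = nested_cv(
                    feats.loc[sids],
                    y,
                    n_features=config.n_features,
                    k_range=config.k_range,
                    seed=int(class_rng.integers(0, 2**31 - 1)),
                    problem=f"{ga} vs {gb}",
                )
                reports.append(rep)
            if reports:
                pd.concat([r.to_frame() for r in reports], ignore_index=True).to_csv(
                    out / "classification.tsv", sep="\t", index=False
                )
                for r in reports:
                    r.attribution.rename("importance").rename_axis("feature").reset_index().to_csv(
                        out / f"attribution_{r.problem.replace(' ', '_')}.tsv", sep="\t", index=False
                    )
        except Exception as exc:  # noqa: BLE001
            raise _fail("classify", None, exc) from exc

    (out / "params.json").write_text(json.dumps(config.to_dict(), indent=2) + "\n")
    log.info("pipeline complete: %s", out)
    return out
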