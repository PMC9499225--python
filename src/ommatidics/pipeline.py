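"""End-to-end analyses on the packaged tables and user data.

``reproduce_main`` re-derives every species-level statistic that the
packaged tables support: the pale/dark partition of the 26 focal species,
the pooled t comparing pale and dark brightness means, Fisher's exact test
on the color x activity table, the pale/dark facet-diameter ratios and
facet-area (sensitivity) folds for the size-matched congener pairs, and
the pale-species survey screen.  Each check carries the published value it
is compared against and a pass/fail flag at print precision (ratios to two
decimals, t to one).

Per-worker raw data behind the species summaries are unpublished, so the
model-fitting battery (MANCOVA, EMMs, letters) is demonstrated on
synthetic workers (see :mod:`ommatidics.synth`) or user-supplied tables,
never on the packaged summaries.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import colorimetry, fixtures, optics, stats
from .model import ConfigurationError, OmmatidicsError, SurveyRecord

__all__ = [
    "CONGENER_PAIRS",
    "PUBLISHED",
    "ReproductionReport",
    "reproduce_main",
    "survey_screen",
    "run_config",
]

logger = logging.getLogger(__name__)

#: size-matched pale/dark congener pairs whose EMM facet-diameter ratios are
#: published (pale species first)
CONGENER_PAIRS = [
    ("Myrmecocystus", "christineae", "yuma"),
    ("Myrmecocystus", "navajo", "kennedyi"),
    ("Myrmecocystus", "mexicanus-02", "mendax-03"),
    ("Aphaenogaster", "megommata", "occidentalis"),
    ("Aphaenogaster", "megommata", "patruelis"),
    ("Aphaenogaster", "megommata", "boulderensis"),
    ("Temnothorax", "BCA-5", "neomexicanus"),
    ("Temnothorax", "BCA-5", "tricarinatus"),
]

#: published values the report checks itself against (print precision)
PUBLISHED = {
    "t": -10.1,
    "t_df": 24,
    "fisher_p_below": 1e-4,
    "n_pale": 10,
    "n_dark": 16,
    "group_mean_pale": 74.6,
    "group_mean_dark": 45.4,
    "d_ratio": {
        ("Myrmecocystus", "christineae", "yuma"): 1.44,
        ("Myrmecocystus", "navajo", "kennedyi"): 1.43,
        ("Myrmecocystus", "mexicanus-02", "mendax-03"): 1.41,
        ("Aphaenogaster", "megommata", "occidentalis"): 1.15,
        ("Aphaenogaster", "megommata", "patruelis"): 1.13,
        ("Aphaenogaster", "megommata", "boulderensis"): 1.23,
        ("Temnothorax", "BCA-5", "neomexicanus"): 1.23,
        ("Temnothorax", "BCA-5", "tricarinatus"): 1.32,
    },
    # facet-area fold bands per genus (pale vs paired dark congeners)
    "fold_bands": {
        "Myrmecocystus": (2.0, 2.1),
        "Aphaenogaster": (1.3, 1.5),
        "Temnothorax": (1.5, 1.7),
    },
    "n_survey_flagged": 21,
}


@dataclass
class ReproductionReport:
    """All fixture-derivable statistics with their published comparisons."""

    partition: Mapping[str, int]
    brightness_test: Mapping[str, float]
    group_means: Mapping[str, float]
    fisher_p: float
    d_ratios: Sequence[Mapping]
    facet_area_folds: Sequence[Mapping]
    survey: Mapping[str, object]
    checks: Mapping[str, bool] = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), indent=2, **kwargs)

    def to_text(self) -> str:
        lines = ["Reproduction report", "===================", ""]
        bt = self.brightness_test
        lines.append(
            f"Pale vs dark species brightness: t = {bt['t']:.1f} ({bt['df']} df), "
            f"p = {bt['p']:.2e}"
        )
        gm = self.group_means
        lines.append(
            f"  recomputed group means: pale {gm['pale']:.1f}, dark {gm['dark']:.1f} "
            f"(published {PUBLISHED['group_mean_pale']}/{PUBLISHED['group_mean_dark']}; "
            "species-mean recomputation differs slightly from the published "
            "worker-level figures)"
        )
        lines.append(
            "Partition: "
            + ", ".join(f"{k} = {v}" for k, v in sorted(self.partition.items()))
        )
        lines.append(f"Color x activity Fisher exact p = {self.fisher_p:.2e}")
        lines.append("")
        lines.append("Facet-diameter EMM ratios (pale/dark):")
        for row in self.d_ratios:
            ok = "ok" if row["matches_published"] else "MISMATCH"
            lines.append(
                f"  {row['genus']:>14} {row['pale']}/{row['dark']}: "
                f"{row['ratio']:.2f} (published {row['published']:.2f}) [{ok}]"
            )
        lines.append("Facet-area (sensitivity) folds:")
        for row in self.facet_area_folds:
            lines.append(
                f"  {row['genus']:>14} {row['pale']}/{row['dark']}: {row['fold']:.2f}"
            )
        sv = self.survey
        lines.append("")
        lines.append(
            f"Survey screen: {sv['n_flagged']}/{sv['n_candidates']} candidate taxa "
            "flagged (pale with enlarged eyes); "
            f"{sv['n_dark_flagged']} dark references flagged"
        )
        lines.append("")
        failed = [k for k, v in self.checks.items() if not v]
        lines.append(
            "All published-value checks passed."
            if not failed
            else f"FAILED checks: {failed}"
        )
        return "\n".join(lines)


def reproduce_main(alpha: float = 0.05) -> ReproductionReport:
    """Recompute the species-level results from the packaged tables."""
    integrity = fixtures.verify_fixtures()
    if not all(integrity.values()):
        bad = {k: v for k, v in integrity.items() if not v}
        raise OmmatidicsError(f"fixture integrity failure: {bad}")

    species = fixtures.load_fixture("table1")
    classes = {
        rec.label: colorimetry.classify_color(rec.brightness_mean, "main_study")
        for rec in species
    }
    partition = {
        c: sum(1 for v in classes.values() if v == c)
        for c in ("pale", "dark", "indeterminate")
    }
    pale_Bs = [r.brightness_mean for r in species if classes[r.label] == "pale"]
    dark_Bs = [r.brightness_mean for r in species if classes[r.label] == "dark"]
    bt = colorimetry.brightness_group_test(pale_Bs, dark_Bs)
    group_means = {
        "pale": float(np.mean(pale_Bs)),
        "dark": float(np.mean(dark_Bs)),
    }

    table2 = fixtures.load_fixture("table2")
    fisher_p = stats.fisher_exact_rxc(table2)

    by_key = {(r.genus, r.species): r for r in species}
    d_ratios, folds = [], []
    for genus, pale, dark in CONGENER_PAIRS:
        dp = by_key[(genus, pale)].facet_diameter_D_emm
        dd = by_key[(genus, dark)].facet_diameter_D_emm
        ratio = optics.diameter_ratio(dp, dd)
        published = PUBLISHED["d_ratio"][(genus, pale, dark)]
        d_ratios.append(
            {
                "genus": genus,
                "pale": pale,
                "dark": dark,
                "D_pale_emm": dp,
                "D_dark_emm": dd,
                "ratio": ratio,
                "published": published,
                "matches_published": round(ratio, 2) == published,
            }
        )
        folds.append(
            {
                "genus": genus,
                "pale": pale,
                "dark": dark,
                "fold": optics.sensitivity_fold(dp, dd),
            }
        )

    candidates = [r for r in fixtures.load_fixture("table5") if r.role == "candidate"]
    dark_refs = fixtures.load_fixture("tableS1")
    flags = survey_screen(candidates, dark_refs)
    dark_flags = survey_screen(dark_refs, dark_refs)
    survey = {
        "n_candidates": len(candidates),
        "n_flagged": sum(flags.values()),
        "flags": {k: bool(v) for k, v in flags.items()},
        "n_dark_flagged": sum(dark_flags.values()),
    }

    checks = {
        "t_matches": round(bt["t"], 1) == PUBLISHED["t"],
        "df_matches": bt["df"] == PUBLISHED["t_df"],
        "fisher_below_1e4": fisher_p < PUBLISHED["fisher_p_below"],
        "partition_matches": partition["pale"] == PUBLISHED["n_pale"]
        and partition["dark"] == PUBLISHED["n_dark"]
        and partition["indeterminate"] == 0,
        "all_ratios_match": all(r["matches_published"] for r in d_ratios),
        "all_candidates_flagged": sum(flags.values()) == PUBLISHED["n_survey_flagged"],
        "no_dark_reference_flagged": sum(dark_flags.values()) == 0,
    }
    for genus, (lo, hi) in PUBLISHED["fold_bands"].items():
        vals = [f["fold"] for f in folds if f["genus"] == genus]
        # the published bands are prefixed "about" and printed to one
        # decimal; allow that decimal as slack (the ratio of the printed
        # D-ratios themselves can fall just outside, e.g. 1.32^2 = 1.74)
        checks[f"folds_in_band_{genus}"] = all(lo - 0.1 <= v <= hi + 0.1 for v in vals)

    return ReproductionReport(
        partition=partition,
        brightness_test=bt,
        group_means=group_means,
        fisher_p=fisher_p,
        d_ratios=d_ratios,
        facet_area_folds=folds,
        survey=survey,
        checks=checks,
    )


def survey_screen(
    candidates: Sequence[SurveyRecord],
    dark_references: Sequence[SurveyRecord],
) -> dict:
    """Flag pale species with enlarged eyes.

    A taxon is flagged when its mean brightness exceeds the survey cutoff
    (B > 70) AND its relative eye size exceeds the largest relative eye
    size among its genus's dark references.  Candidates in a genus with no
    dark reference are skipped with a warning (not flagged).
    Returns ``{"genus species": bool}``.
    """
    dark_max: dict = {}
    for ref in dark_references:
        if ref.role != "dark_reference":
            continue
        prev = dark_max.get(ref.genus, -math.inf)
        dark_max[ref.genus] = max(prev, ref.relative_eye_size)
    flags = {}
    for rec in candidates:
        key = f"{rec.genus} {rec.species}"
        if rec.genus not in dark_max:
            logger.warning("no dark reference for genus %s; skipping %s", rec.genus, key)
            continue
        is_pale = (
            not math.isnan(rec.brightness_mean)
            and colorimetry.classify_color(rec.brightness_mean, "survey") == "pale"
        )
        flags[key] = bool(is_pale and rec.relative_eye_size > dark_max[rec.genus])
    return flags


_ALLOWED_KEYS = {"analyses", "alpha", "output_dir", "data", "mancova"}
_ALLOWED_ANALYSES = {"reproduce", "survey", "mancova"}
_ALLOWED_MANCOVA_KEYS = {"responses", "group", "covariate", "alpha", "emm_at"}


def run_config(path) -> dict:
    """Execute the analyses requested by a YAML/JSON config file.

    Schema::

        analyses: [reproduce, survey, mancova]   # required, non-empty
        alpha: 0.05                              # optional default alpha
        output_dir: out/                         # optional; write reports
        data: workers.csv                        # required for mancova
        mancova:
          responses: [eye_area, facet_count, facet_diameter_D]
          group: species_id
          covariate: mesosoma_length
          alpha: 0.01                            # per-analysis post-hoc alpha
          emm_at: null

    Unknown keys raise a schema error naming them.  Returns the report
    bundle as a dict (also written as JSON + text when ``output_dir`` is
    given).
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(cfg)}")
    unknown = set(cfg) - _ALLOWED_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    analyses = cfg.get("analyses")
    if not analyses or not isinstance(analyses, list):
        raise ConfigurationError("config needs a non-empty 'analyses' list")
    bad = set(analyses) - _ALLOWED_ANALYSES
    if bad:
        raise ConfigurationError(f"unknown analyses: {sorted(bad)}")
    alpha = float(cfg.get("alpha", 0.05))

    bundle: dict = {}
    text_parts = []
    if "reproduce" in analyses or "survey" in analyses:
        report = reproduce_main(alpha=alpha)
        if "reproduce" in analyses:
            bundle["reproduce"] = asdict(report)
            text_parts.append(report.to_text())
        if "survey" in analyses:
            bundle["survey"] = dict(report.survey)
    if "mancova" in analyses:
        mc = cfg.get("mancova")
        if not isinstance(mc, dict):
            raise ConfigurationError("'mancova' analysis needs a 'mancova' mapping")
        unknown = set(mc) - _ALLOWED_MANCOVA_KEYS
        if unknown:
            raise ConfigurationError(f"unknown mancova keys: {sorted(unknown)}")
        if "data" not in cfg:
            raise ConfigurationError("'mancova' analysis needs a 'data' CSV path")
        import pandas as pd

        df = pd.read_csv(cfg["data"])
        fit = stats.fit_mancova(
            df,
            responses=list(mc["responses"]),
            group_factor=mc["group"],
            covariate=mc.get("covariate"),
            emm_at=mc.get("emm_at"),
            alpha=float(mc.get("alpha", alpha)),
        )
        bundle["mancova"] = {
            "wilks_lambda": fit.wilks.statistic,
            "wilks_F": fit.wilks.F,
            "wilks_df": [fit.wilks.df_num, fit.wilks.df_den],
            "wilks_p": fit.wilks.p,
            "pillai_trace": fit.pillai.statistic,
            "pillai_p": fit.pillai.p,
            "evaluation_point": fit.evaluation_point,
            "emm": fit.emm_table.to_dict(orient="records"),
            "letters": {r: dict(fit.posthoc[r].letters) for r in fit.responses},
            "per_response": {
                r: {"F": t.F, "df": [t.df_num, t.df_den], "p": t.p}
                for r, t in fit.per_response.items()
            },
        }
        text_parts.append(
            "MANCOVA: Wilks lambda = {:.3f}, F({:.0f}, {:.1f}) = {:.2f}, p = {:.3g}".format(
                fit.wilks.statistic,
                fit.wilks.df_num,
                fit.wilks.df_den,
                fit.wilks.F,
                fit.wilks.p,
            )
        )

    out_dir = cfg.get("output_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(bundle, indent=2, default=float))
        (out / "report.txt").write_text("\n\n".join(text_parts) + "\n")
    return bundle
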