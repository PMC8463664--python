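"""Trait definitions and coding for the poison-frog parental-care dataset.

Raw per-species records carry the study's variables: caregiver and
tadpole-transporter sex, adult habitat, tadpole deposition site, larval
cannibalism, male/female snout-vent length (mm), clutch size, egg diameter
(mm), tadpole length at Gosner stage 25 (mm), number of tadpoles carried, the
11-segment coloration indicators (or their 0-11 sum), and the skin-alkaloid
level (ug per 100 mg skin).

Coding rules
------------
* conspicuousness score = sum of the 11 binary segment indicators (0-11);
  a species is *conspicuous* iff the score is >= 6.  Presence/absence of
  dorsal stripe, lateral stripe and flash markings is kept as metadata and
  does not enter the sum.
* alkaloids are *present* iff the level is strictly greater than
  10 ug / 100 mg skin (a level of exactly 10 codes as absent).
* caregiver sex is binarized male/female; species with no parental care, or
  biparental care with no dominant sex, are excluded with a machine-readable
  reason.
* transporter sex follows the majority of observations; exact ties are
  treated as missing, not assigned.
* deposition is binarized phytotelm (1) vs non-phytotelm (0); species using
  both ponds and streams are non-phytotelm.
* SSD = female SVL / male SVL.
* range-valued numeric fields ("lo-hi") reduce to the midpoint of the range;
  continuous traits are natural-log transformed; egg size, clutch size and
  tadpole size are additionally size-controlled by regressing on (log)
  female SVL under phylogenetic GLS, keeping the residuals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import PhyloTree, normalize_name

__all__ = [
    "conspicuousness_score",
    "binarize_conspicuous",
    "alkaloid_presence",
    "sexual_size_dimorphism",
    "code_caregiver",
    "code_transporter",
    "code_deposition",
    "code_habitat",
    "code_cannibalism",
    "median_of_range",
    "parse_numeric_or_range",
    "log_transform",
    "size_controlled_residuals",
    "read_trait_table",
    "code_trait_table",
    "CodingResult",
]

SEGMENT_COLUMNS = [f"seg_{i}" for i in range(1, 12)]

RAW_COLUMNS = [
    "species",
    "caregiver",
    "transporter",
    "transporter_obs_male",
    "transporter_obs_female",
    "habitat",
    "deposition",
    "cannibalism",
    "male_svl",
    "female_svl",
    "clutch_size",
    "egg_size",
    "tadpole_size",
    "n_tadpoles_carried",
    "conspicuousness_score",
    "alkaloid_ug_per_100mg",
]


# ---------------------------------------------------------------------------
# scalar coding operations
# ---------------------------------------------------------------------------


def conspicuousness_score(segments) -> int:
    """Sum of the 11 binary skin-segment indicators (0 = no contrast, 11 = max)."""
    seg = list(segments)
    if len(seg) != 11:
        raise ValueError(f"need exactly 11 segment indicators, got {len(seg)}")
    vals = []
    for s in seg:
        f = float(s)
        if f not in (0.0, 1.0):
            raise ValueError(f"segment indicators must be 0 or 1, got {s!r}")
        vals.append(int(f))
    return int(sum(vals))


def binarize_conspicuous(score) -> int:
    """1 iff the 0-11 coloration score is >= 6."""
    s = float(score)
    if not 0 <= s <= 11:
        raise ValueError(f"score must lie in [0, 11], got {score!r}")
    return int(s >= 6)


def alkaloid_presence(level) -> int:
    """1 iff the skin-alkaloid level exceeds 10 ug per 100 mg skin (strict >)."""
    x = float(level)
    if x < 0:
        raise ValueError(f"alkaloid level must be non-negative, got {level!r}")
    return int(x > 10.0)


def sexual_size_dimorphism(female_svl, male_svl) -> float:
    """Female/male snout-vent length ratio; missing if either sex is missing."""
    f, m = float(female_svl), float(male_svl)
    if np.isnan(f) or np.isnan(m):
        return float("nan")
    if f <= 0 or m <= 0:
        raise ValueError("body sizes must be positive")
    return f / m


_EXCLUDE_NO_CARE = "no_parental_care"
_EXCLUDE_AMBIGUOUS = "ambiguous_biparental_care"
_MISSING_TIE = "transporter_sex_tie"


def code_caregiver(raw) -> tuple:
    """Binarize caregiver sex.

    Returns ``(code, reason)`` with code in {'male', 'female', 'excluded'} or
    nan for unknown; excluded species (no apparent care, or biparental care
    with no dominant sex) carry a machine-readable reason.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return (float("nan"), None)
    v = str(raw).strip().lower()
    if v in ("", "na", "unknown"):
        return (float("nan"), None)
    if v == "male":
        return ("male", None)
    if v == "female":
        return ("female", None)
    if v == "none":
        return ("excluded", _EXCLUDE_NO_CARE)
    if v == "both":
        return ("excluded", _EXCLUDE_AMBIGUOUS)
    raise ValueError(f"unrecognised caregiver value {raw!r}")


def code_transporter(raw, obs_male=None, obs_female=None) -> tuple:
    """Sex of the tadpole-carrying parent, assigned by observed majority.

    When both sexes transport, the majority of observation counts decides
    (e.g. a 5:1 male:female ratio codes male); an exact tie, or 'both'
    without counts, is missing rather than arbitrarily assigned.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return (float("nan"), None)
    v = str(raw).strip().lower()
    if v in ("", "na", "unknown"):
        return (float("nan"), None)
    if v == "male":
        return ("male", None)
    if v == "female":
        return ("female", None)
    if v == "none":
        return ("excluded", _EXCLUDE_NO_CARE)
    if v == "both":
        om = float(obs_male) if obs_male is not None and not pd.isna(obs_male) else np.nan
        of = float(obs_female) if obs_female is not None and not pd.isna(obs_female) else np.nan
        if np.isnan(om) or np.isnan(of) or om == of:
            return (float("nan"), _MISSING_TIE)
        return (("male", None) if om > of else ("female", None))
    raise ValueError(f"unrecognised transporter value {raw!r}")


def code_deposition(raw) -> float:
    """1 for phytotelm breeding, 0 for streams/ponds (or both), nan unknown."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return float("nan")
    v = str(raw).strip().lower()
    if v in ("", "na", "unknown"):
        return float("nan")
    if v in ("stream", "pond", "multiple", "stream+pond", "pond+stream"):
        return 0.0
    if v in ("phytotelm", "phytotelmata"):
        return 1.0
    raise ValueError(f"unrecognised deposition value {raw!r}")


def code_habitat(raw) -> float:
    """1 for home ranges away from streams, 0 for riparian, nan unknown."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return float("nan")
    v = str(raw).strip().lower()
    if v in ("", "na", "unknown"):
        return float("nan")
    if v == "near_stream":
        return 0.0
    if v == "far_stream":
        return 1.0
    raise ValueError(f"unrecognised habitat value {raw!r}")


def code_cannibalism(raw) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return float("nan")
    v = str(raw).strip().lower()
    if v in ("", "na", "unknown"):
        return float("nan")
    if v == "present":
        return 1.0
    if v == "absent":
        return 0.0
    raise ValueError(f"unrecognised cannibalism value {raw!r}")


def median_of_range(lo, hi) -> float:
    """Midpoint of a reported lo-hi range (the median of the range)."""
    lo, hi = float(lo), float(hi)
    if lo > hi:
        raise ValueError(f"range low {lo} exceeds high {hi}")
    return (lo + hi) / 2.0


_RANGE_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+)\s*[-–]\s*([0-9]*\.?[0-9]+)\s*$")


def parse_numeric_or_range(value) -> float:
    """Parse a numeric cell, reducing 'lo-hi' range strings to their median."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return float("nan")
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value).strip()
    if s == "" or s.upper() == "NA":
        return float("nan")
    m = _RANGE_RE.match(s)
    if m:
        return median_of_range(float(m.group(1)), float(m.group(2)))
    return float(s)


def log_transform(values) -> np.ndarray:
    """Natural log; missing propagates, non-positive values are rejected by name."""
    arr = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~np.isnan(arr) & (arr <= 0))
    if bad.size:
        if isinstance(values, pd.Series):
            names = list(values.index[bad])
        else:
            names = bad.tolist()
        raise ValueError(f"log transform requires positive values; offenders: {names}")
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    out[ok] = np.log(arr[ok])
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    return out


def size_controlled_residuals(
    trait, female_svl, tree: PhyloTree, species=None, method: str = "pgls"
):
    """Residuals of a trait regressed on female body size.

    Under ``method='pgls'`` (default) the regression uses Brownian
    phylogenetic GLS, consistent with the rest of the pipeline;
    ``method='ols'`` gives ordinary least squares.  Missing values propagate;
    fewer than 3 complete pairs among tree species is rejected.
    """
    from .regression import pgls_residuals

    t = pd.Series(np.asarray(trait, dtype=float))
    f = pd.Series(np.asarray(female_svl, dtype=float))
    if species is None:
        species = list(tree.tip_labels)[: len(t)]
    species = [normalize_name(s) for s in species]
    in_tree = pd.Series([s in set(tree.tip_labels) for s in species])
    ok = (~t.isna()) & (~f.isna()) & in_tree
    if int(ok.sum()) < 3:
        raise ValueError("need at least 3 complete trait/size pairs present in tree")
    sub_species = [s for s, o in zip(species, ok) if o]
    resid = pgls_residuals(
        t[ok].to_numpy(), f[ok].to_numpy(), tree, taxa=sub_species, method=method
    )
    out = np.full(len(t), np.nan)
    out[np.flatnonzero(ok.to_numpy())] = resid
    return out


# ---------------------------------------------------------------------------
# table-level coding
# ---------------------------------------------------------------------------


@dataclass
class CodingResult:
    coded: pd.DataFrame
    exclusions: pd.DataFrame


def read_trait_table(path) -> pd.DataFrame:
    """Read the raw species-by-trait CSV ('NA' = missing, ranges as 'lo-hi')."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "species" not in df.columns:
        raise ValueError("trait table must have a 'species' column")
    df["species"] = df["species"].map(normalize_name)
    if df["species"].duplicated().any():
        dup = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species rows: {dup}")
    return df.set_index("species")


def _num(df, col) -> pd.Series:
    if col not in df.columns:
        return pd.Series(np.nan, index=df.index)
    return df[col].map(parse_numeric_or_range)


def _cat(df, col) -> pd.Series:
    if col not in df.columns:
        return pd.Series(np.nan, index=df.index)
    return df[col].replace({"": np.nan, "NA": np.nan})


def code_trait_table(
    raw: pd.DataFrame, tree: PhyloTree | None = None, residual_method: str = "pgls"
) -> CodingResult:
    """Apply every coding rule to a raw table; deterministic by construction.

    Returns the coded table (one row per species, numeric columns with nan for
    missing) and an exclusions table (species, field, reason).  Residual
    (size-controlled) traits are computed only when a tree is supplied.
    """
    if len(raw) == 0:
        raise ValueError("empty trait table")
    df = raw
    idx = df.index
    exclusions = []

    coded = pd.DataFrame(index=idx)
    # conspicuousness: use segment indicators when present, else the raw score
    if all(c in df.columns for c in SEGMENT_COLUMNS):
        seg = df[SEGMENT_COLUMNS].apply(lambda col: col.map(parse_numeric_or_range))
        have = seg.notna().all(axis=1)
        score = pd.Series(np.nan, index=idx)
        score[have] = [
            conspicuousness_score(row) for row in seg[have].to_numpy()
        ]
        raw_score = _num(df, "conspicuousness_score")
        score = score.fillna(raw_score)
    else:
        score = _num(df, "conspicuousness_score")
    bad_scores = score.dropna()[(score.dropna() < 0) | (score.dropna() > 11)]
    if len(bad_scores):
        raise ValueError(
            f"conspicuousness scores out of [0, 11]: {list(bad_scores.index)}"
        )
    coded["coloration_score"] = score
    coded["conspicuous"] = score.map(
        lambda s: np.nan if pd.isna(s) else float(binarize_conspicuous(s))
    )

    alk = _num(df, "alkaloid_ug_per_100mg")
    if (alk.dropna() < 0).any():
        raise ValueError("negative alkaloid levels")
    coded["alkaloid_level"] = alk
    coded["alkaloids_present"] = alk.map(
        lambda a: np.nan if pd.isna(a) else float(alkaloid_presence(a))
    )

    care_codes, trans_codes = [], []
    for sp in idx:
        code, reason = code_caregiver(_cat(df, "caregiver").get(sp))
        if code == "excluded":
            exclusions.append((sp, "caregiver", reason))
            care_codes.append(np.nan)
        else:
            care_codes.append({"male": 0.0, "female": 1.0}.get(code, np.nan))
        code, reason = code_transporter(
            _cat(df, "transporter").get(sp),
            _num(df, "transporter_obs_male").get(sp),
            _num(df, "transporter_obs_female").get(sp),
        )
        if code == "excluded":
            exclusions.append((sp, "transporter", _EXCLUDE_NO_CARE))
            trans_codes.append(np.nan)
        elif isinstance(code, float) and np.isnan(code) and reason == _MISSING_TIE:
            exclusions.append((sp, "transporter", _MISSING_TIE))
            trans_codes.append(np.nan)
        else:
            trans_codes.append({"male": 0.0, "female": 1.0}.get(code, np.nan))
    coded["caregiver_female"] = care_codes
    coded["transporter_female"] = trans_codes
    coded["phytotelm_breeder"] = _cat(df, "deposition").map(code_deposition)
    coded["habitat_far"] = _cat(df, "habitat").map(code_habitat)
    coded["cannibalism"] = _cat(df, "cannibalism").map(code_cannibalism)

    male_svl = _num(df, "male_svl")
    female_svl = _num(df, "female_svl")
    for name, series in (("male_svl", male_svl), ("female_svl", female_svl)):
        if (series.dropna() <= 0).any():
            raise ValueError(f"non-positive {name}")
    coded["ssd"] = [
        sexual_size_dimorphism(f, m) if not (pd.isna(f) or pd.isna(m)) else np.nan
        for f, m in zip(female_svl, male_svl)
    ]
    coded["female_svl"] = female_svl

    for col, out in (
        ("clutch_size", "log_clutch_size"),
        ("egg_size", "log_egg_size"),
        ("tadpole_size", "log_tadpole_size"),
        ("n_tadpoles_carried", "log_n_tadpoles"),
    ):
        coded[out] = log_transform(_num(df, col))

    if tree is not None:
        logf = log_transform(female_svl)
        for src, out in (
            ("log_egg_size", "residual_egg_size"),
            ("log_clutch_size", "residual_clutch_size"),
            ("log_tadpole_size", "residual_tadpole_size"),
        ):
            pairs = (~coded[src].isna()) & (~logf.isna())
            pairs &= pd.Series(
                [s in set(tree.tip_labels) for s in idx], index=idx
            )
            if int(pairs.sum()) >= 3:
                coded[out] = size_controlled_residuals(
                    coded[src].to_numpy(),
                    logf.to_numpy(),
                    tree,
                    species=list(idx),
                    method=residual_method,
                )
            else:
                coded[out] = np.nan

    excl = pd.DataFrame(exclusions, columns=["species", "field", "reason"])
    return CodingResult(coded=coded, exclusions=excl)
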