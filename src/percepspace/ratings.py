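"""Rater screening and conversion of Likert similarity ratings to dissimilarities.

Raw data are per-rater similarity scores ``s`` on an integer 1–9 Likert scale
(1 = maximally dissimilar, 9 = maximally similar) for unordered image pairs,
each pair rated twice per rater, with identical-image catch trials to detect
inattention. The pipeline is:

1. screen raters (catch failure, low volume, low agreement, low entropy),
2. convert similarity to raw dissimilarity ``d = 10 - s``,
3. min–max normalize each rater's dissimilarities to [0, 1],
4. average normalized values per pair into a :class:`DissimilarityTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityRating",
    "RaterProfile",
    "DissimilarityTable",
    "ExclusionConfig",
    "load_ratings",
    "similarity_to_dissimilarity",
    "normalize_rater",
    "aggregate_pairs",
    "compute_rater_cc",
    "response_entropy",
    "exclude_raters",
]

RATING_COLUMNS = [
    "rater_id",
    "image_i",
    "image_j",
    "score",
    "repetition",
    "is_catch",
    "catch_response",
]


class InvalidRatingError(ValueError):
    """A rating record violates the schema (e.g. score outside 1–9)."""


class DegenerateRaterError(ValueError):
    """A rater used a single raw value for every pair; min–max range is zero."""


@dataclass(frozen=True)
class SimilarityRating:
    """One Likert similarity judgment of an unordered image pair."""

    rater_id: str
    pair: tuple[str, str]
    s: int
    repetition: int = 1
    is_catch: bool = False
    catch_response: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= int(self.s) <= 9:
            raise InvalidRatingError(
                f"score {self.s!r} outside 1-9 for rater {self.rater_id!r}, pair {self.pair!r}"
            )
        i, j = self.pair
        object.__setattr__(self, "pair", (min(i, j), max(i, j)))
        if self.is_catch and self.pair[0] != self.pair[1]:
            raise InvalidRatingError(
                f"catch trial with distinct images {self.pair!r} (rater {self.rater_id!r})"
            )


@dataclass
class RaterProfile:
    """Per-rater screening statistics and the exclusion verdict."""

    rater_id: str
    n_unique_pairs: int = 0
    passed_catch: bool = True
    cc_vs_others: float | None = None
    response_entropy: float = 0.0
    excluded: bool = False
    reason: str | None = None


@dataclass
class DissimilarityTable:
    """Symmetric map ``unordered pair -> mean normalized dissimilarity`` in [0, 1]."""

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    n_ratings: dict[tuple[str, str], int] = field(default_factory=dict)

    @staticmethod
    def _key(i: str, j: str) -> tuple[str, str]:
        return (i, j) if i <= j else (j, i)

    def get(self, i: str, j: str) -> float:
        return self.entries[self._key(i, j)]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self.entries

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self.entries)

    def ids(self) -> list[str]:
        seen: set[str] = set()
        for i, j in self.entries:
            seen.add(i)
            seen.add(j)
        return sorted(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"image_i": i, "image_j": j, "dbar": self.entries[(i, j)], "n_ratings": self.n_ratings[(i, j)]}
            for i, j in self.pairs()
        ]
        return pd.DataFrame(rows, columns=["image_i", "image_j", "dbar", "n_ratings"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DissimilarityTable":
        table = cls()
        n_col = df["n_ratings"] if "n_ratings" in df.columns else np.ones(len(df), dtype=int)
        for (i, j, d), n in zip(df[["image_i", "image_j", "dbar"]].itertuples(index=False), np.asarray(n_col)):
            key = cls._key(str(i), str(j))
            table.entries[key] = float(d)
            table.n_ratings[key] = int(n)
        return table

    @classmethod
    def from_csv(cls, path) -> "DissimilarityTable":
        return cls.from_frame(pd.read_csv(path, dtype={"image_i": str, "image_j": str}))


@dataclass
class ExclusionConfig:
    """Thresholds for the four screening rules.

    min_pairs
        Rule (b): raters with fewer unique rated pairs are dropped (default 30).
    sd_cut
        Rules (c)/(d): drop raters more than this many SDs below the
        population mean of agreement c.c. / response entropy (default 2).
    min_overlap
        Minimum shared pairs for a rater's agreement c.c. to be defined.
    """

    min_pairs: int = 30
    sd_cut: float = 2.0
    min_overlap: int = 10


def load_ratings(path_or_df) -> pd.DataFrame:
    """Read a ratings CSV (or normalize a DataFrame) into canonical form.

    Expected columns: ``rater_id,image_i,image_j,score,repetition,is_catch,
    catch_response``. Pairs are reordered so image_i <= image_j; scores are
    validated against the 1–9 Likert range.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, dtype={"rater_id": str, "image_i": str, "image_j": str})
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidRatingError(f"ratings table missing columns {missing}")
    df["rater_id"] = df["rater_id"].astype(str)
    df["image_i"] = df["image_i"].astype(str)
    df["image_j"] = df["image_j"].astype(str)
    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = df.index[~scores.isin(range(1, 10))]
    if len(bad):
        row = df.loc[bad[0]]
        raise InvalidRatingError(
            f"score {row['score']!r} outside 1-9 (rater {row['rater_id']!r}, "
            f"pair ({row['image_i']!r}, {row['image_j']!r}))"
        )
    df["score"] = scores.astype(int)
    df["is_catch"] = df["is_catch"].astype(bool)
    swap = df["image_i"] > df["image_j"]
    df.loc[swap, ["image_i", "image_j"]] = df.loc[swap, ["image_j", "image_i"]].to_numpy()
    catch_bad = df["is_catch"] & (df["image_i"] != df["image_j"])
    if catch_bad.any():
        row = df[catch_bad].iloc[0]
        raise InvalidRatingError(
            f"catch trial with distinct images ({row['image_i']!r}, {row['image_j']!r})"
        )
    return df


def similarity_to_dissimilarity(s) -> np.ndarray | int:
    """Convert Likert similarity to raw dissimilarity, ``d = 10 - s``."""
    arr = np.asarray(s)
    if not np.all((arr >= 1) & (arr <= 9) & (arr == np.round(arr))):
        offending = arr[~((arr >= 1) & (arr <= 9) & (arr == np.round(arr)))]
        raise InvalidRatingError(f"score(s) outside 1-9: {offending[:5].tolist()}")
    d = 10 - arr
    return d if arr.ndim else int(d)


def normalize_rater(raw: np.ndarray) -> np.ndarray:
    """Min–max normalize one rater's raw dissimilarities onto [0, 1].

    Raises DegenerateRaterError when the rater's range is zero (a rater who
    used a single response value carries no ordinal information).
    """
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        raise DegenerateRaterError(f"zero range: all raw dissimilarities equal {lo}")
    return (raw - lo) / (hi - lo)


def response_entropy(scores: np.ndarray) -> float:
    """Shannon entropy (nats) of a rater's score histogram over the 9 Likert bins."""
    counts = np.bincount(np.asarray(scores, dtype=int), minlength=10)[1:10]
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _rater_pair_means(df: pd.DataFrame) -> pd.DataFrame:
    """Mean raw score per (rater, pair), repetitions averaged, catch trials dropped."""
    real = df[~df["is_catch"]]
    return (
        real.groupby(["rater_id", "image_i", "image_j"])["score"]
        .mean()
        .rename("score")
        .reset_index()
    )


def compute_rater_cc(df: pd.DataFrame, rater_id: str, min_overlap: int = 10) -> float | None:
    """Pearson c.c. of one rater against the leave-that-rater-out mean.

    Computed on the raw 1–9 scale, averaging the rater's repetitions per pair
    first, over pairs also rated by at least one other rater. Returns None
    when fewer than ``min_overlap`` such pairs exist or either side has zero
    variance.
    """
    means = _rater_pair_means(df)
    mine = means[means["rater_id"] == rater_id]
    others = means[means["rater_id"] != rater_id]
    if mine.empty or others.empty:
        return None
    other_mean = others.groupby(["image_i", "image_j"])["score"].mean().rename("other")
    merged = mine.join(other_mean, on=["image_i", "image_j"], how="inner")
    if len(merged) < min_overlap:
        return None
    a = merged["score"].to_numpy(float)
    b = merged["other"].to_numpy(float)
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def _all_rater_ccs(df: pd.DataFrame, min_overlap: int) -> dict[str, float | None]:
    """Leave-one-out c.c. for every rater, vectorized over the pair-mean table."""
    means = _rater_pair_means(df)
    totals = means.groupby(["image_i", "image_j"])["score"].agg(["sum", "count"])
    merged = means.join(totals, on=["image_i", "image_j"])
    # leave-one-out mean of the other raters' per-pair means
    merged = merged[merged["count"] > 1]
    merged["other"] = (merged["sum"] - merged["score"]) / (merged["count"] - 1)
    out: dict[str, float | None] = {}
    for rid, grp in merged.groupby("rater_id"):
        if len(grp) < min_overlap:
            out[rid] = None
            continue
        a = grp["score"].to_numpy(float)
        b = grp["other"].to_numpy(float)
        if a.std() == 0 or b.std() == 0:
            out[rid] = None
        else:
            out[rid] = float(np.corrcoef(a, b)[0, 1])
    for rid in df["rater_id"].unique():
        out.setdefault(rid, None)
    return out


def exclude_raters(
    df: pd.DataFrame, config: ExclusionConfig | None = None
) -> tuple[pd.DataFrame, list[RaterProfile]]:
    """Apply the four screening rules; return retained ratings and all profiles.

    Rules, in order, each applied to the survivors of the previous ones:

    a. failed the identical-image catch question;
    b. rated fewer than ``min_pairs`` unique pairs;
    c. agreement c.c. vs the other raters more than ``sd_cut`` SDs below the
       population mean (raters with undefined c.c. are not excluded here);
    d. response entropy more than ``sd_cut`` SDs below the population mean.

    Population means/SDs for (c) and (d) are frozen over the raters surviving
    (a) and (b); they are not re-estimated as raters drop out, so the
    procedure is idempotent.
    """
    config = config or ExclusionConfig()
    df = load_ratings(df)
    profiles: dict[str, RaterProfile] = {}

    real = df[~df["is_catch"]]
    pair_counts = real.groupby("rater_id").apply(
        lambda g: g[["image_i", "image_j"]].drop_duplicates().shape[0], include_groups=False
    )
    catch = df[df["is_catch"]]
    failed_catch = set()
    for rid, grp in catch.groupby("rater_id"):
        responses = grp["catch_response"].astype(str).str.lower()
        if (responses != "same").any():
            failed_catch.add(rid)

    for rid in df["rater_id"].unique():
        profiles[rid] = RaterProfile(
            rater_id=rid,
            n_unique_pairs=int(pair_counts.get(rid, 0)),
            passed_catch=rid not in failed_catch,
            response_entropy=response_entropy(real[real["rater_id"] == rid]["score"].to_numpy())
            if (real["rater_id"] == rid).any()
            else 0.0,
        )

    # rules (a) and (b)
    for prof in profiles.values():
        if not prof.passed_catch:
            prof.excluded, prof.reason = True, "catch"
        elif prof.n_unique_pairs < config.min_pairs:
            prof.excluded, prof.reason = True, "min_pairs"

    survivors_ab = [rid for rid, p in profiles.items() if not p.excluded]
    df_ab = df[df["rater_id"].isin(survivors_ab)]
    ccs = _all_rater_ccs(df_ab, config.min_overlap)
    for rid in survivors_ab:
        profiles[rid].cc_vs_others = ccs.get(rid)

    defined = np.array([c for c in (ccs.get(r) for r in survivors_ab) if c is not None])
    if defined.size >= 2:
        cc_cut = defined.mean() - config.sd_cut * defined.std()
        for rid in survivors_ab:
            c = profiles[rid].cc_vs_others
            if c is not None and c < cc_cut:
                profiles[rid].excluded, profiles[rid].reason = True, "low_cc"

    ent = np.array([profiles[r].response_entropy for r in survivors_ab])
    if ent.size >= 2:
        ent_cut = ent.mean() - config.sd_cut * ent.std()
        for rid in survivors_ab:
            if profiles[rid].excluded:
                continue
            if profiles[rid].response_entropy < ent_cut:
                profiles[rid].excluded, profiles[rid].reason = True, "low_entropy"

    retained_ids = [rid for rid, p in profiles.items() if not p.excluded]
    if len(retained_ids) < 3:
        raise ValueError(f"only {len(retained_ids)} raters retained; pipeline needs >= 3")
    retained = df[df["rater_id"].isin(retained_ids)].copy()
    order = {rid: k for k, rid in enumerate(df["rater_id"].unique())}
    return retained, sorted(profiles.values(), key=lambda p: order[p.rater_id])


def aggregate_pairs(df: pd.DataFrame) -> DissimilarityTable:
    """Normalize each rater and average normalized dissimilarities per pair.

    Input is a (screened) ratings table. Each rater's scores are converted to
    raw dissimilarities d = 10 - s, min–max normalized over all of that
    rater's ratings (both repetitions, catch trials excluded), and then every
    pair's retained ratings — both repetitions, all raters — are averaged.
    """
    df = load_ratings(df)
    real = df[~df["is_catch"]].copy()
    if real.empty:
        raise ValueError("no non-catch ratings to aggregate")
    real["d_raw"] = 10 - real["score"]
    parts = []
    for rid, grp in real.groupby("rater_id"):
        try:
            norm = normalize_rater(grp["d_raw"].to_numpy())
        except DegenerateRaterError as exc:
            raise DegenerateRaterError(f"rater {rid!r}: {exc}") from exc
        g = grp.copy()
        g["d_norm"] = norm
        parts.append(g)
    allnorm = pd.concat(parts)
    table = DissimilarityTable()
    for (i, j), grp in allnorm.groupby(["image_i", "image_j"]):
        key = DissimilarityTable._key(i, j)
        table.entries[key] = float(grp["d_norm"].mean())
        table.n_ratings[key] = int(len(grp))
    return table


def profiles_to_frame(profiles: list[RaterProfile]) -> pd.DataFrame:
    """Exclusion report as a DataFrame, one row per rater."""
    return pd.DataFrame(
        [
            {
                "rater_id": p.rater_id,
                "n_unique_pairs": p.n_unique_pairs,
                "passed_catch": p.passed_catch,
                "cc_vs_others": p.cc_vs_others,
                "response_entropy": p.response_entropy,
                "excluded": p.excluded,
                "reason": p.reason or "",
            }
            for p in profiles
        ]
    )
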