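"""Human-classifier agreement metrics and the blindfolded binomial null.

Two competing summaries of an nAFC response table are implemented:

* **mean agreement** — the mean over participants of the percentage of trials
  on which the participant's choice equals the classifier's label. This is the
  degree-of-agreement measure.
* **counting metric** — the percentage of participants *credited* as agreeing:
  full credit for an agreement count above the chance expectation
  ``c = n_trials * p_chance``, half credit at exactly ``c`` (the rule reduces
  to "2+ trials count, 1 trial counts half" when c = 1).

The "blindfolded" null gives the analytic distribution of agreement counts for
an observer choosing uniformly at random: ``K ~ Binomial(n_trials, p_chance)``.
Under that null the counting metric sits near 45% for 48 trials at p = 1/48
while mean agreement sits at chance (~2.08%) — the contrast that motivates
reporting the mean.

The :class:`AgreementModel` / :class:`AgreementResults` pair wraps these
metrics in a fit/results interface: build the model from a response table
(or CSV), call :meth:`~AgreementModel.fit`, and read estimates, tests and a
``summary()`` table off the results object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from advagree.cohort import ALTERNATIVES_SEP, validate_response_table

__all__ = [
    "BinomialNull",
    "AgreementSummary",
    "PairwiseAgreement",
    "blindfolded_null",
    "counting_credit",
    "mean_agreement",
    "counting_metric",
    "per_image_analysis",
    "pairwise_agreement",
    "AgreementModel",
    "AgreementResults",
]


@dataclass(frozen=True)
class BinomialNull:
    """Chance model for agreement counts: K ~ Binomial(n_trials, p_chance)."""

    n_trials: int = 48
    p_chance: float = 1.0 / 48.0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 < self.p_chance < 1.0:
            raise ValueError("p_chance must lie in (0, 1)")

    @property
    def chance_count(self) -> float:
        """Expected number of agreeing trials under the null."""
        return self.n_trials * self.p_chance

    @property
    def chance_pct(self) -> float:
        return 100.0 * self.p_chance


@dataclass
class AgreementSummary:
    """Cohort-level agreement estimates for one experiment."""

    mean_agreement_pct: float
    counting_metric_pct: float | None
    n_participants: int
    n_trials: int
    chance_pct: float
    mean_agreeing_images: float
    per_participant_agreement: np.ndarray = field(repr=False, default=None)


@dataclass
class PairwiseAgreement:
    """Probabilities that two random raters (networks and/or humans) agree."""

    p_net_net: float
    p_net_human: float
    p_human_human: float
    n_net_net: int
    n_net_human: int
    n_human_human: int


def counting_credit(k: int, chance_count: float) -> float:
    """Credit one participant under the counting rule.

    With an integer chance count *c*: 1 above *c*, 0.5 at exactly *c*, else 0.
    With a non-integer *c* no participant can land exactly on chance, so credit
    is 1 above *c* and 0 otherwise (no half credit).
    """
    c = chance_count
    if abs(c - round(c)) < 1e-9:
        c = round(c)
        return 1.0 if k > c else (0.5 if k == c else 0.0)
    return 1.0 if k > c else 0.0


def blindfolded_null(null: BinomialNull) -> tuple[np.ndarray, float]:
    """Analytic blindfolded null: agreement-count pmf and expected counting metric.

    Returns ``(pmf, expected_pct)`` where ``pmf[k]`` is the binomial probability
    of agreeing on exactly *k* of ``null.n_trials`` trials when guessing
    uniformly, and ``expected_pct`` is the counting metric (in percent) such a
    blindfolded cohort would show in expectation.
    """
    k = np.arange(null.n_trials + 1)
    pmf = sps.binom.pmf(k, null.n_trials, null.p_chance)
    credits = np.array([counting_credit(int(i), null.chance_count) for i in k])
    return pmf, float(100.0 * np.dot(pmf, credits))


def _per_participant_counts(table: pd.DataFrame) -> pd.DataFrame:
    agree = (table["chosen_label"] == table["machine_label"]).astype(int)
    g = table.assign(_agree=agree).groupby("participant_id")["_agree"]
    out = g.agg(n_agree="sum", n_trials="count")
    if (out["n_trials"] == 0).any():
        raise ValueError("participant with zero trials")
    return out


def mean_agreement(table: pd.DataFrame, chance_pct: float | None = None) -> AgreementSummary:
    """Mean over participants of the percentage of trials matching the machine label.

    Also reports the mean count of agreeing images per participant (the
    "x/48 images" figure). ``chance_pct`` defaults to the mean of 100/m over
    trials, m being the number of alternatives offered.
    """
    validate_response_table(table)
    if len(table) == 0:
        raise ValueError("response table is empty")
    counts = _per_participant_counts(table)
    per_pct = 100.0 * counts["n_agree"] / counts["n_trials"]
    if chance_pct is None:
        m = table["alternatives"].map(lambda s: s.count(ALTERNATIVES_SEP)) + 1
        chance_pct = float((100.0 / m).mean())
    n_trials = int(round(counts["n_trials"].mean()))
    return AgreementSummary(
        mean_agreement_pct=float(per_pct.mean()),
        counting_metric_pct=None,
        n_participants=len(counts),
        n_trials=n_trials,
        chance_pct=float(chance_pct),
        mean_agreeing_images=float(counts["n_agree"].mean()),
        per_participant_agreement=per_pct.to_numpy(),
    )


def counting_metric(table: pd.DataFrame, null: BinomialNull) -> float:
    """Percent of participants credited as agreeing under the counting rule.

    Every participant must have exactly ``null.n_trials`` responses. See
    :func:`counting_credit` for the crediting rule.
    """
    validate_response_table(table)
    counts = _per_participant_counts(table)
    if not (counts["n_trials"] == null.n_trials).all():
        bad = counts.index[counts["n_trials"] != null.n_trials][0]
        raise ValueError(
            f"participant {bad!r} has {counts.loc[bad, 'n_trials']} trials, "
            f"null expects {null.n_trials}"
        )
    credits = counts["n_agree"].map(lambda k: counting_credit(int(k), null.chance_count))
    return float(100.0 * credits.mean())


def machine_label_rank(chosen: pd.Series, machine_label: str) -> tuple[int, str]:
    """Competition rank of the machine label among chosen labels, plus the mode.

    Labels with equal frequency share the minimum rank; a machine label that was
    never chosen ranks one past the number of distinct chosen labels. The modal
    label breaks frequency ties lexicographically for determinism.
    """
    freq = chosen.value_counts()
    modal = sorted(freq.index[freq == freq.max()])[0]
    if machine_label not in freq.index:
        return len(freq) + 1, modal
    rank = 1 + int((freq > freq[machine_label]).sum())
    return rank, modal


def per_image_analysis(
    table: pd.DataFrame, null: BinomialNull, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-image agreement: exact binomial tests, modal label and machine-label rank.

    For each image, tests whether the number of participants choosing the
    machine label exceeds chance (one-sided exact binomial test at
    ``null.p_chance``). Raw p-values are reported together with a
    Bonferroni-corrected significance flag at ``alpha``.
    """
    validate_response_table(table)
    if len(table) == 0:
        raise ValueError("response table is empty")
    rows = []
    n_images = table["image_id"].nunique()
    for image_id, grp in table.groupby("image_id", sort=True):
        n_total = len(grp)
        machine = grp["machine_label"].iloc[0]
        n_agree = int((grp["chosen_label"] == machine).sum())
        test = sps.binomtest(n_agree, n_total, null.p_chance, alternative="greater")
        rank, modal = machine_label_rank(grp["chosen_label"], machine)
        rows.append(
            {
                "image_id": image_id,
                "n_agree": n_agree,
                "n_total": n_total,
                "agreement_pct": 100.0 * n_agree / n_total,
                "binomial_p_value": test.pvalue,
                "machine_label": machine,
                "modal_label": modal,
                "machine_label_rank": rank,
                "significant_bonferroni": bool(test.pvalue < alpha / n_images),
            }
        )
    return pd.DataFrame(rows)


def pairwise_agreement(
    network_labels: pd.DataFrame, human_table: pd.DataFrame
) -> PairwiseAgreement:
    """Agreement probabilities among networks, among humans, and across.

    Parameters
    ----------
    network_labels : DataFrame
        Wide table, one row per image (index = image id), one column per
        network, entries = the label each network assigns.
    human_table : DataFrame
        A response table; a participant contributes comparisons only for images
        they actually saw.

    Each probability is the fraction of agreeing comparisons among all possible
    comparisons: image x unordered network pair (net-net), image x network x
    participant response (net-human), and image x unordered participant pair
    (human-human).
    """
    if network_labels.shape[1] < 2:
        raise ValueError("need >= 2 networks")
    validate_response_table(human_table)

    def _pairs_agree(labels: np.ndarray) -> tuple[int, int]:
        n = len(labels)
        total = n * (n - 1) // 2
        _, counts = np.unique(labels.astype(str), return_counts=True)
        agree = int(np.sum(counts * (counts - 1) // 2))
        return agree, total

    nn_agree = nn_total = 0
    for _, row in network_labels.iterrows():
        a, t = _pairs_agree(row.to_numpy())
        nn_agree += a
        nn_total += t

    nh_agree = nh_total = 0
    hh_agree = hh_total = 0
    for image_id, grp in human_table.groupby("image_id"):
        if image_id not in network_labels.index:
            continue
        net_row = network_labels.loc[image_id].to_numpy().astype(str)
        choices = grp["chosen_label"].to_numpy().astype(str)
        nh_agree += int(np.sum(choices[:, None] == net_row[None, :]))
        nh_total += len(choices) * len(net_row)
        a, t = _pairs_agree(choices)
        hh_agree += a
        hh_total += t
    if hh_total == 0:
        raise ValueError("need >= 2 participants per image for human-human comparisons")
    return PairwiseAgreement(
        p_net_net=nn_agree / nn_total,
        p_net_human=nh_agree / nh_total,
        p_human_human=hh_agree / hh_total,
        n_net_net=nn_total,
        n_net_human=nh_total,
        n_human_human=hh_total,
    )


# ---------------------------------------------------------------------------
# model / results interface


class AgreementModel:
    """Agreement analysis of an nAFC response table, statsmodels-style.

    Parameters
    ----------
    table : DataFrame
        Long-format response table (see :data:`advagree.cohort.RESPONSE_COLUMNS`).
    null : BinomialNull, optional
        Chance model. If omitted it is inferred from the table: ``n_trials`` =
        the (common) per-participant trial count and ``p_chance`` = 1/m for the
        (common) number of alternatives; inference fails informatively when
        these vary.

    Examples
    --------
    >>> model = AgreementModel.from_csv("responses.csv")   # doctest: +SKIP
    >>> res = model.fit()                                  # doctest: +SKIP
    >>> print(res.summary())                               # doctest: +SKIP
    """

    def __init__(self, table: pd.DataFrame, null: BinomialNull | None = None):
        validate_response_table(table)
        if len(table) == 0:
            raise ValueError("response table is empty")
        self.table = table.reset_index(drop=True)
        self.null = self._infer_null(table) if null is None else null

    @staticmethod
    def _infer_null(table: pd.DataFrame) -> BinomialNull:
        trials = table.groupby("participant_id").size()
        if trials.nunique() != 1:
            raise ValueError("per-participant trial counts vary; pass an explicit BinomialNull")
        m = (table["alternatives"].map(lambda s: s.count(ALTERNATIVES_SEP)) + 1).unique()
        if len(m) != 1:
            raise ValueError("number of alternatives varies; pass an explicit BinomialNull")
        return BinomialNull(n_trials=int(trials.iloc[0]), p_chance=1.0 / int(m[0]))

    @classmethod
    def from_csv(cls, path, null: BinomialNull | None = None) -> "AgreementModel":
        from advagree.io import read_response_table

        return cls(read_response_table(path), null=null)

    def fit(self, alpha: float = 0.05) -> "AgreementResults":
        """Compute all agreement metrics and the test against chance."""
        from advagree.stats import one_sample_test

        summary = mean_agreement(self.table, chance_pct=self.null.chance_pct)
        summary.counting_metric_pct = counting_metric(self.table, self.null)
        per_image = per_image_analysis(self.table, self.null, alpha=alpha)
        _, expected_counting = blindfolded_null(self.null)
        vals = summary.per_participant_agreement
        ttest = one_sample_test(vals, self.null.chance_pct) if np.std(vals, ddof=1) > 0 else None
        return AgreementResults(
            model=self,
            summary_=summary,
            per_image_=per_image,
            expected_counting_pct_=expected_counting,
            chance_test_=ttest,
            alpha=alpha,
        )


class AgreementResults:
    """Fitted agreement metrics with uncertainty, diagnostics and a summary table."""

    def __init__(self, model, summary_, per_image_, expected_counting_pct_, chance_test_, alpha):
        self.model = model
        self.summary_ = summary_
        self.per_image_ = per_image_
        self.expected_counting_pct_ = expected_counting_pct_
        self.chance_test_ = chance_test_
        self.alpha = alpha

    @property
    def mean_agreement_pct(self) -> float:
        return self.summary_.mean_agreement_pct

    @property
    def counting_metric_pct(self) -> float:
        return self.summary_.counting_metric_pct

    def conf_int(self) -> tuple[float, float]:
        """Normal-approximation CI for mean agreement (percent)."""
        vals = self.summary_.per_participant_agreement
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        tcrit = sps.t.ppf(1 - self.alpha / 2, len(vals) - 1)
        return float(vals.mean() - tcrit * se), float(vals.mean() + tcrit * se)

    def summary(self) -> str:
        """Human-readable summary table (percentages to 2 decimals)."""
        s = self.summary_
        lo, hi = self.conf_int()
        lines = [
            "Agreement analysis",
            "=" * 58,
            f"participants            {s.n_participants:>10d}",
            f"trials per participant  {s.n_trials:>10d}",
            f"chance                  {s.chance_pct:>9.2f}%",
            f"mean agreement          {s.mean_agreement_pct:>9.2f}%"
            f"  ({s.mean_agreeing_images:.2f}/{s.n_trials} images)",
            f"  {100 * (1 - self.alpha):.0f}% CI               [{lo:.2f}%, {hi:.2f}%]",
            f"counting metric         {s.counting_metric_pct:>9.2f}%",
            f"  blindfolded expects   {self.expected_counting_pct_:>9.2f}%",
        ]
        if self.chance_test_ is not None:
            t = self.chance_test_
            lines.append(
                f"t vs chance             t({t.dof:.0f}) = {t.statistic:.2f}, "
                f"p = {t.p_value:.3g}, d = {t.effect_size:.2f}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        s = self.summary_
        d = {
            "mean_agreement_pct": s.mean_agreement_pct,
            "counting_metric_pct": s.counting_metric_pct,
            "mean_agreeing_images": s.mean_agreeing_images,
            "n_participants": s.n_participants,
            "n_trials": s.n_trials,
            "chance_pct": s.chance_pct,
            "expected_counting_pct_blindfolded": self.expected_counting_pct_,
            "null": asdict(self.model.null),
            "per_image": self.per_image_.to_dict(orient="records"),
        }
        if self.chance_test_ is not None:
            d["chance_test"] = asdict(self.chance_test_)
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def plot_per_image(self, ax=None):
        """Bar plot of per-image agreement with the chance line (skew diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        df = self.per_image_.sort_values("agreement_pct", ascending=False)
        ax.bar(range(len(df)), df["agreement_pct"], color="steelblue")
        ax.axhline(self.summary_.chance_pct, color="crimson", ls="--", label="chance")
        ax.set_xlabel("image (sorted)")
        ax.set_ylabel("agreement (%)")
        ax.legend()
        return ax
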