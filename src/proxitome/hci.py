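"""High-confidence interactor (HCI) filtering across six comparisons.

Two TurboID experiments give six bait-vs-reference datasets: per terminus
(N-terminal and C-terminal fusion) a comparison to control in experiment 1,
to control in experiment 2 and to the DNA-adjacent dCas9:TurboID control in
experiment 2. A protein is a high-confidence interactor when it is

* nuclear,
* enriched (p below the HCI level with positive log2 fold change) in at
  least two of the six datasets, and
* per terminus, enriched in either 0 of 3 datasets (exclusive to the other
  terminus) or in >= 2 of 3 datasets.

"Not tested" (protein absent from a dataset) counts as not enriched:
absence of evidence cannot contribute to a high-confidence call.
"""

from __future__ import annotations

import pandas as pd

from .containers import GeneList
from .errors import ValidationError

NT_SLOTS = (
    "nt_kdm5_vs_control_exp1",
    "nt_kdm5_vs_control_exp2",
    "nt_kdm5_vs_dcas9_exp2",
)
CT_SLOTS = (
    "ct_kdm5_vs_control_exp1",
    "ct_kdm5_vs_control_exp2",
    "ct_kdm5_vs_dcas9_exp2",
)
ALL_SLOTS = NT_SLOTS + CT_SLOTS

ENRICHED = "enriched"
NOT_ENRICHED = "not_enriched"
NOT_TESTED = "not_tested"


def call_significant(results: dict[str, pd.DataFrame],
                     alpha_hci: float = 0.1) -> pd.DataFrame:
    """Per-protein calls across the six comparison slots.

    ``results`` maps each canonical slot name to a volcano table (the output
    of :func:`proxitome.enrichment.run_comparison`). A protein is
    ``enriched`` in a slot when ``p < alpha_hci`` (strict) and its log2
    fold change is positive; excluded proteins and proteins absent from a
    table are ``not_tested``.
    """
    got = set(results)
    expected = set(ALL_SLOTS)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise ValidationError(
            f"comparison slots mismatch: missing={missing}, unexpected={extra}"
        )
    proteins = sorted(set().union(*(set(df.index) for df in results.values())))
    calls = pd.DataFrame(NOT_TESTED, index=pd.Index(proteins, name="protein_id"),
                         columns=list(ALL_SLOTS))
    for slot in ALL_SLOTS:
        df = results[slot]
        tested = df["pvalue"].notna()
        if "excluded_reason" in df.columns:
            tested &= df["excluded_reason"].fillna("").astype(str) == ""
        enriched = tested & (df["pvalue"] < alpha_hci) & (df["log2fc"] > 0)
        calls.loc[df.index[tested], slot] = NOT_ENRICHED
        calls.loc[df.index[enriched], slot] = ENRICHED
    return calls


def hci_rule(k_nt: int, k_ct: int) -> bool:
    """The count-based clause of the high-confidence rule (nuclear gate aside)."""
    return (k_nt + k_ct >= 2) and (k_nt == 0 or k_nt >= 2) and (k_ct == 0 or k_ct >= 2)


def apply_hci_workflow(calls: pd.DataFrame, nuclear: GeneList | set
                       ) -> pd.DataFrame:
    """Evaluate the filtering workflow; one record per protein.

    Returns a table with per-terminus enriched counts, the nuclear flag,
    the ``hci`` decision, a category (``shared`` when both termini have
    >= 2 of 3, ``nt_exclusive``/``ct_exclusive`` when the other terminus
    has 0) and, for rejected proteins, the first failing gate. The nuclear
    gate is applied last so near-miss non-nuclear proteins stay auditable.
    """
    for slot in ALL_SLOTS:
        if slot not in calls.columns:
            raise ValidationError(f"call matrix lacks slot {slot!r}")
    nuclear_set = nuclear.as_set if isinstance(nuclear, GeneList) else set(nuclear)
    k_nt = (calls[list(NT_SLOTS)] == ENRICHED).sum(axis=1)
    k_ct = (calls[list(CT_SLOTS)] == ENRICHED).sum(axis=1)
    records = []
    for protein in calls.index:
        knt, kct = int(k_nt[protein]), int(k_ct[protein])
        is_nuclear = protein in nuclear_set
        counts_ok = hci_rule(knt, kct)
        hci = counts_ok and is_nuclear
        if hci:
            if knt >= 2 and kct >= 2:
                category, reason = "shared", ""
            elif kct == 0:
                category, reason = "nt_exclusive", ""
            else:
                category, reason = "ct_exclusive", ""
        else:
            category = "rejected"
            if knt + kct < 2:
                reason = "fewer_than_2_of_6"
            elif not counts_ok:
                reason = "terminus_inconsistent"
            else:
                reason = "non_nuclear"
        records.append((protein, knt, kct, is_nuclear, hci, category, reason))
    out = pd.DataFrame(
        records,
        columns=["protein_id", "k_nt", "k_ct", "nuclear", "hci",
                 "category", "rejection_reason"],
    ).set_index("protein_id")
    return out


def null_hci_probability(p_enriched_per_slot: float) -> float:
    """Nominal probability that a null protein passes the count rule.

    Under the null a protein is called enriched in one dataset with
    probability ``p_enriched_per_slot`` (about alpha/2 at level alpha, since
    the direction requirement halves the two-sided rate), independently
    across the six slots. Used to bound expected false-positive
    contamination of the HCI set.
    """
    from math import comb

    p = p_enriched_per_slot
    pmf = [comb(3, k) * p ** k * (1 - p) ** (3 - k) for k in range(4)]
    return sum(pmf[a] * pmf[b]
               for a in range(4) for b in range(4) if hci_rule(a, b))


def hci_set(hci_table: pd.DataFrame) -> frozenset[str]:
    return frozenset(hci_table.index[hci_table["hci"]])


def recover_known_interactors(sets: dict[str, set | frozenset],
                              known: GeneList) -> pd.DataFrame:
    """Recovery of a known-interactor list by one or more candidate sets.

    For each named set: the intersection members, their count and the
    fraction of the known list recovered (exact fraction kept, a
    whole-percent rendering provided for display).
    """
    if len(known) == 0:
        raise ValidationError("known-interactor list is empty")
    rows = []
    for name in sets:
        hit = sorted(known.as_set & set(sets[name]))
        frac = len(hit) / len(known)
        rows.append((name, len(hit), len(known), frac, round(frac * 100),
                     ",".join(hit)))
    return pd.DataFrame(
        rows, columns=["set_name", "n_recovered", "n_known", "fraction",
                       "percent", "members"],
    ).set_index("set_name")
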