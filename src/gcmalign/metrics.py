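"""Sum-of-pairs alignment error: SPFP, SPFN and their average.

Two alignments over the same sequences are compared through the homologous
residue pairs they assert (two upper-case residues sharing a column).
SPFP is the fraction of the estimate's pairs absent from the reference
(false positives); SPFN the fraction of the reference's pairs absent from
the estimate (false negatives); "SP error" is their mean.  Lower-case
letters assert nothing on either side — scores on compressed alignments
therefore reflect only the homology they still claim.

Counting is column-wise (each column contributes C(u, 2) pairs, and shared
pairs are found by bucketing a column's residues by their column in the
other alignment), so no quadratic pair set is materialized.
"""

from __future__ import annotations

from dataclasses import dataclass

from .msa import GAP, Alignment, restrict


@dataclass(frozen=True)
class SPResult:
    spfp: float
    spfn: float
    sp_error: float
    shared_pairs: int
    estimated_pairs: int
    reference_pairs: int

    def as_dict(self) -> dict:
        return {
            "spfp": self.spfp,
            "spfn": self.spfn,
            "sp_error": self.sp_error,
            "shared_pairs": self.shared_pairs,
            "estimated_pairs": self.estimated_pairs,
            "reference_pairs": self.reference_pairs,
        }


def pair_counts(alignment: Alignment) -> int:
    """Number of homologous pairs asserted: Σ_columns C(upper_count, 2)."""
    total = 0
    for col in range(alignment.length):
        u = alignment.upper_count(col)
        total += u * (u - 1) // 2
    return total


def _upper_site_columns(alignment: Alignment) -> dict[tuple[str, int], int]:
    """Map (row_id, ungapped_site) -> column, for upper-case cells only."""
    mapping: dict[tuple[str, int], int] = {}
    for rid, row in alignment.rows():
        site = -1
        for col, ch in enumerate(row):
            if ch == GAP:
                continue
            site += 1
            if ch.isupper():
                mapping[(rid, site)] = col
    return mapping


def compare_alignments(estimated: Alignment, reference: Alignment) -> SPResult:
    """SPFP/SPFN of an estimated alignment against a reference.

    The reference's rows must be a subset of the estimate's; the estimate is
    first restricted to them (the convention for small curated references
    embedded in large datasets).  Per-row ungapped sequences must agree.
    An alignment asserting zero pairs contributes 0 to its rate.
    """
    ref_ids = set(reference.row_ids)
    if not ref_ids <= set(estimated.row_ids):
        missing = sorted(ref_ids - set(estimated.row_ids))
        raise ValueError(f"reference rows missing from estimate: {missing}")
    est = restrict(estimated, ref_ids)
    for rid in reference.row_ids:
        if est.ungapped(rid) != reference.ungapped(rid):
            raise ValueError(
                f"sequence mismatch between estimate and reference for {rid!r}"
            )
    n_est = pair_counts(est)
    n_ref = pair_counts(reference)
    ref_map = _upper_site_columns(reference)
    shared = 0
    site_counters = {rid: -1 for rid in est.row_ids}
    for col in range(est.length):
        buckets: dict[int, int] = {}
        for rid in est.row_ids:
            ch = est.row(rid)[col]
            if ch == GAP:
                continue
            site_counters[rid] += 1
            if not ch.isupper():
                continue
            ref_col = ref_map.get((rid, site_counters[rid]))
            if ref_col is not None:
                buckets[ref_col] = buckets.get(ref_col, 0) + 1
        for g in buckets.values():
            shared += g * (g - 1) // 2
    spfp = (n_est - shared) / n_est if n_est else 0.0
    spfn = (n_ref - shared) / n_ref if n_ref else 0.0
    return SPResult(
        spfp=spfp,
        spfn=spfn,
        sp_error=(spfp + spfn) / 2.0,
        shared_pairs=shared,
        estimated_pairs=n_est,
        reference_pairs=n_ref,
    )
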