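"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Reporting of clinical rates uses half-up rounding (0.5 -> 1), not the
    banker's rounding of the builtin ``round``.
    """
    exp = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(exp, rounding=ROUND_HALF_UP))


def check_allele_counts(counts) -> None:
    """Validate an allele-count table: non-negative, reads conserved.

    Raises ValueError on negative counts or rows where
    ref + alt + other != depth.
    """
    import numpy as np

    required = {"site_id", "depth", "ref_count", "alt_count", "other_count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"allele-count table missing columns: {sorted(missing)}")
    arr = counts[["depth", "ref_count", "alt_count", "other_count"]].to_numpy()
    if (arr < 0).any():
        raise ValueError("negative values in allele-count table")
    total = counts[["ref_count", "alt_count", "other_count"]].sum(axis=1)
    if not np.array_equal(total.to_numpy(), counts["depth"].to_numpy()):
        raise ValueError("ref_count + alt_count + other_count != depth at some sites")
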