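"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementation paths: the Fisher
oracle enumerates every 2x2 table with the observed margins in exact
rational arithmetic, and the segregation oracle transcribes the dominant
co-segregation rule clause by clause over explicit member lists.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_oracle(a: int, b: int, c: int, d: int, side: str) -> Fraction:
    """Exact Fisher p by full hypergeometric enumeration (rational arithmetic)."""
    r1, r2, s = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or s == 0 or s == n:
        return Fraction(1)
    k_min, k_max = max(0, s - r2), min(r1, s)
    # all tables share the denominator comb(n, s); compare numerators exactly
    weight = {k: comb(r1, k) * comb(r2, s - k) for k in range(k_min, k_max + 1)}
    total = sum(weight.values())
    obs = weight[a]
    if side == "greater":
        kept = sum(v for k, v in weight.items() if k >= a)
    else:
        kept = sum(v for v in weight.values() if v <= obs)
    return Fraction(kept, total)


def segregation_oracle(variant, pedigree, policy) -> str:
    """Literal clause-by-clause evaluation of the dominant segregation rule."""
    def genotype(m):
        g = variant.genotypes.get(m.id)
        return None if g is None or g.gt == "./." else g.gt

    affected = [m for m in pedigree.members if m.affection == "affected"]
    unaffected = [m for m in pedigree.members if m.affection == "unaffected"]
    typed_affected = [m for m in affected if genotype(m) is not None]
    untyped_affected = [m for m in affected if genotype(m) is None]

    # clause 1: a genotyped affected non-carrier disqualifies
    if any(genotype(m) == "0/0" for m in typed_affected):
        return "FAILS"
    # clause 2: unaffected carriers above the tolerance disqualify
    n_unaff_carriers = sum(1 for m in unaffected if genotype(m) in ("0/1", "1/1"))
    if n_unaff_carriers > policy.allow_unaffected_carriers:
        return "FAILS"
    # clause 3: missing affected genotypes under the "fail" policy disqualify
    if untyped_affected and policy.missing_genotype_handling == "fail":
        return "FAILS"
    # clause 4: without any genotyped affected carrier nothing is decidable
    if not typed_affected:
        return "INDETERMINATE"
    # clause 5: missing affected genotypes block a positive call by default
    if (
        untyped_affected
        and policy.require_all_affected_carriers
        and policy.missing_genotype_handling == "indeterminate"
    ):
        return "INDETERMINATE"
    # clause 6: every genotyped affected member carries the variant
    return "SEGREGATES"


def bh_oracle(p_values):
    """Hand-executed Benjamini-Hochberg step-up: p~(i) = min_{j>=i} m p(j)/j."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * p_values[i] / rank)
        adjusted[i] = running_min
    return adjusted
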