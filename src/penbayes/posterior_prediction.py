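"""Bayesian posteriors per variant and prospective estimates for all missense.

A variant's calibrated prior (from the EM regression) is combined with its
observed affected/unaffected counts by conjugate update; variants never yet
observed in a carrier keep their prior as the prospective estimate.  The
module also enumerates the missense space of a protein, either exhaustively
(19 substitutions per residue) or restricted to amino-acid changes reachable
by a single nucleotide change of the coding sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .em_calibration import VariantPrior
from .empirical_bayes import BetaParams, credible_interval
from .variant_data import AMINO_ACIDS, HeterozygoteCounts

__all__ = [
    "PenetranceEstimate",
    "bayesian_posterior",
    "prospective_estimate",
    "enumerate_missense",
    "write_estimates",
    "read_estimates",
]

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class PenetranceEstimate:
    """Prior and posterior penetrance for one variant with a credible interval."""

    key: tuple[int, str, str]
    prior_mean: float
    posterior_mean: float
    ci_low: float
    ci_high: float
    alpha_post: float
    beta_post: float
    provenance: str  # "observed" | "prospective"


def bayesian_posterior(counts: HeterozygoteCounts, prior: VariantPrior,
                       level: float = 0.95) -> PenetranceEstimate:
    """Conjugate update of a variant-specific prior with observed counts."""
    a_post = counts.affected + prior.alpha_em
    b_post = counts.unaffected + prior.beta_em
    lo, hi = credible_interval(BetaParams(a_post, b_post), level)
    return PenetranceEstimate(
        key=prior.key,
        prior_mean=prior.mean,
        posterior_mean=a_post / (a_post + b_post),
        ci_low=lo,
        ci_high=hi,
        alpha_post=a_post,
        beta_post=b_post,
        provenance="observed" if counts.total > 0 else "prospective",
    )


def prospective_estimate(prior: VariantPrior,
                         level: float = 0.95) -> PenetranceEstimate:
    """Estimate for a variant with no observed carriers: posterior = prior."""
    return bayesian_posterior(HeterozygoteCounts(0, 0), prior, level)


def _translate(cds: str) -> str:
    prot = []
    for i in range(0, len(cds) - 2, 3):
        aa = _CODON_TABLE[cds[i:i + 3]]
        if aa == "*":
            if i + 3 < len(cds):
                raise ValueError(
                    f"internal stop codon at nucleotide {i + 1}")
            break
        prot.append(aa)
    return "".join(prot)


def enumerate_missense(protein_sequence: Optional[str] = None,
                       coding_sequence: Optional[str] = None
                       ) -> list[tuple[int, str, str]]:
    """Enumerate missense variant keys for a protein.

    With ``protein_sequence``: every substitution to one of the 19 other
    standard amino acids at every residue (19 L keys).  With
    ``coding_sequence``: only amino-acid changes reachable by a single
    nucleotide change of some codon, deduplicated at the amino-acid level
    (synonymous and stop-gain changes excluded).  If both are given, their
    translations must agree.
    """
    if coding_sequence is not None:
        cds = coding_sequence.strip().upper().replace("U", "T")
        if len(cds) % 3 not in (0,):
            raise ValueError("coding sequence length must be a multiple of 3")
        prot = _translate(cds)
        if protein_sequence is not None and prot != protein_sequence.upper():
            raise ValueError(
                "coding sequence translation disagrees with protein sequence")
        keys = []
        for pos0 in range(len(prot)):
            codon = cds[3 * pos0: 3 * pos0 + 3]
            ref = prot[pos0]
            alts = set()
            for j in range(3):
                for base in "ACGT":
                    if base == codon[j]:
                        continue
                    aa = _CODON_TABLE[codon[:j] + base + codon[j + 1:]]
                    if aa not in ("*", ref):
                        alts.add(aa)
            keys.extend((pos0 + 1, ref, alt) for alt in sorted(alts))
        return keys
    if protein_sequence is None:
        raise ValueError(
            "provide a protein sequence or a coding sequence; exhaustive "
            "enumeration needs the reference residue at each position")
    seq = protein_sequence.strip().upper()
    return [(i + 1, ref, alt)
            for i, ref in enumerate(seq)
            for alt in AMINO_ACIDS if alt != ref]


_COLUMNS = ["variant", "position", "ref", "alt", "prior_mean",
            "posterior_mean", "ci_low", "ci_high", "alpha_post", "beta_post",
            "provenance"]


def write_estimates(estimates: Iterable[PenetranceEstimate], path) -> None:
    """Write estimates as a deterministic CSV sorted by (position, ref, alt)."""
    rows = []
    for e in sorted(estimates, key=lambda e: e.key):
        pos, ref, alt = e.key
        rows.append({
            "variant": f"p.{ref}{pos}{alt}",
            "position": pos, "ref": ref, "alt": alt,
            "prior_mean": f"{e.prior_mean:.6f}",
            "posterior_mean": f"{e.posterior_mean:.6f}",
            "ci_low": f"{e.ci_low:.6f}",
            "ci_high": f"{e.ci_high:.6f}",
            "alpha_post": f"{e.alpha_post:.6f}",
            "beta_post": f"{e.beta_post:.6f}",
            "provenance": e.provenance,
        })
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_estimates(path) -> list[PenetranceEstimate]:
    """Read back an estimates CSV written by :func:`write_estimates`."""
    df = pd.read_csv(path, dtype={"ref": str, "alt": str})
    return [
        PenetranceEstimate(
            key=(int(r.position), r.ref, r.alt),
            prior_mean=float(r.prior_mean),
            posterior_mean=float(r.posterior_mean),
            ci_low=float(r.ci_low), ci_high=float(r.ci_high),
            alpha_post=float(r.alpha_post), beta_post=float(r.beta_post),
            provenance=r.provenance)
        for r in df.itertuples()
    ]
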