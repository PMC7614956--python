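import numpy as np
import pytest

from dropcrispr.annotation import Genome, revcomp

# The published 190-bp example synthesis oligo and its four guide payloads.
PRINTED_OLIGO = (
    "TCAGTCGATCGgctcttcaaggAAGATATACGTTATTGATATgttagaagagcgctcttctagg"
    "GGAAGGAATATTGAGCAACAgttagaagagcgctcttctaggGCGGGTAACGACAACGAAGT"
    "gttagaagagcgctcttctaggTCTCGATTCACCAAACCCTTgttcgaagagcGCTAGCTCCAT"
)
PRINTED_GUIDES = (
    "AAGATATACGTTATTGATAT",
    "GGAAGGAATATTGAGCAACA",
    "GCGGGTAACGACAACGAAGT",
    "TCTCGATTCACCAAACCCTT",
)


@pytest.fixture
def printed_oligo() -> str:
    return PRINTED_OLIGO


@pytest.fixture
def printed_guides() -> tuple[str, ...]:
    return PRINTED_GUIDES


def random_genome(seed: int, length: int, n_chroms: int = 1) -> Genome:
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return Genome(
        {
            f"chr{i + 1}": "".join(rng.choice(bases, size=length))
            for i in range(n_chroms)
        }
    )


def brute_force_pam_scan(genome: Genome, k: int = 20):
    """Position-by-position double-strand NGG scan (testing oracle)."""
    sites = []
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        for i in range(len(seq)):
            # + strand: protospacer [i, i+k), PAM [i+k, i+k+3) == NGG
            if i + k + 3 <= len(seq):
                pam = seq[i + k : i + k + 3]
                proto = seq[i : i + k]
                if pam[1:] == "GG" and "N" not in proto + pam:
                    sites.append((chrom, "+", i, proto, pam))
            # - strand: bottom protospacer whose PAM shows as CCN on top
            if i - 3 >= 0 and i + k <= len(seq):
                top_pam = seq[i - 3 : i]
                top_proto = seq[i : i + k]
                if top_pam[:2] == "CC" and "N" not in top_proto + top_pam:
                    sites.append(
                        (chrom, "-", i, revcomp(top_proto), revcomp(top_pam))
                    )
    sites.sort(key=lambda s: (s[0], s[2], s[1]))
    return sites
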