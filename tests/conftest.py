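import numpy as np
import pytest

from retromethyl.features import DEResult, GenomicFeature


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_de(fid, log2fc, padj=None, pvalue=None, tool="generic", subtype="CMS1"):
    return DEResult(feature_id=fid, log2fc=log2fc, pvalue=pvalue, padj=padj,
                    tool=tool, subtype=subtype)


def make_feature(fid, start, end, strand="+", chrom="chr1", kind="locus"):
    return GenomicFeature(feature_id=fid, kind=kind, chrom=chrom,
                          start=start, end=end, strand=strand)


def random_features(rng, n, kind, chrom_choices=("chr1",), max_pos=1_000_000,
                    max_len=5_000):
    feats = []
    for i in range(n):
        start = int(rng.integers(1, max_pos))
        length = int(rng.integers(1, max_len))
        feats.append(GenomicFeature(
            feature_id=f"{kind}{i}", kind=kind,
            chrom=str(rng.choice(chrom_choices)),
            start=start, end=start + length - 1,
            strand="+" if rng.random() < 0.5 else "-",
        ))
    return feats
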