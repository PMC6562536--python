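import numpy as np
import pytest

from cisreg.core import ChainAlignment, Element, GenomicInterval, Peak


@pytest.fixture(scope="session")
def demo_manifest(tmp_path_factory):
    """One full synthetic-study run shared by the end-to-end assertions."""
    import warnings

    from cisreg.pipeline import run_demo

    outdir = tmp_path_factory.mktemp("demo")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = run_demo(5, outdir)
    return manifest, outdir


def make_peak(chrom="chr1", start=1000, end=2000, summit=None, pvalue=1e-5,
              mark="H3K27ac", name="pk", rpm_ip=None, rpm_input=None):
    iv = GenomicInterval(chrom, start, end)
    return Peak(iv, summit if summit is not None else iv.midpoint, pvalue,
                mark, name=name, rpm_ip=rpm_ip, rpm_input=rpm_input)


def make_element(chrom="chr1", start=1000, end=3000, element_class="enhancer",
                 element_id="el", rpm_ip=None, summit=None):
    iv = GenomicInterval(chrom, start, end)
    return Element(element_id=element_id, interval=iv,
                   summit=summit if summit is not None else iv.midpoint,
                   element_class=element_class, rpm_ip=rpm_ip)


def identity_chain(chrom="chr1", size=100_000, chain_id=1):
    """A single-block chain mapping a chromosome onto itself."""
    return ChainAlignment(
        chain_id=chain_id, score=1e5, s_chrom=chrom, s_size=size,
        s_start=0, s_end=size, t_chrom=chrom, t_size=size, t_strand="+",
        t_start=0, t_end=size, blocks=[(size, 0, 0)],
    )


def random_chains(rng, n_chains=3, n_blocks=12, block_max=200, gap_max=120):
    """Small random chains (gapped; the last one reverse-strand) whose block
    sizes are tiny enough for per-base oracles."""
    chains = []
    s_size = 20_000
    for ci in range(n_chains):
        s_start = int(rng.integers(0, 4_000))
        blocks = []
        for b in range(n_blocks):
            size = int(rng.integers(1, block_max))
            dt = int(rng.integers(0, gap_max))
            dq = int(rng.integers(0, gap_max))
            blocks.append((size, dt, dq))
        blocks[-1] = (blocks[-1][0], 0, 0)
        s_span = sum(sz + dt for sz, dt, _ in blocks)
        t_span = sum(sz + dq for sz, _, dq in blocks)
        t_start = int(rng.integers(0, 2_000))
        chains.append(
            ChainAlignment(
                chain_id=ci + 1, score=1000.0, s_chrom="chr1", s_size=s_size,
                s_start=s_start, s_end=s_start + s_span,
                t_chrom=f"tchr{ci + 1}", t_size=t_start + t_span + 1_000,
                t_strand="-" if ci == n_chains - 1 else "+",
                t_start=t_start, t_end=t_start + t_span, blocks=blocks,
            )
        )
    return chains


def per_base_target_positions(interval, chain):
    """Independent per-base oracle: map every base of ``interval`` through
    ``chain`` one base at a time; returns {source_pos: forward_target_pos}."""
    out = {}
    cur_s, cur_q = chain.s_start, chain.t_start
    for size, dt, dq in chain.blocks:
        for o in range(size):
            s = cur_s + o
            if interval.start <= s < interval.end:
                out[s] = chain.target_forward(cur_q + o)
        cur_s += size + dt
        cur_q += size + dq
    return out
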