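"""Clip the 3' adapter off reads and find the insert-length inference limit.

With 100-nt reads and a minimum 8-base adapter match, the adapter of an
insert up to 92 nt is still visible; from 93 nt on it falls off the read,
so those tags only bound the RNA length from below.
"""

from capscape import DEFAULT_ADAPTER, clip_adapter

fill = "ACGTGGTTCAGATCCGATACGGAAC" * 8

for insert_len in (30, 92, 93):
    read = (fill[:insert_len] + DEFAULT_ADAPTER + fill[::-1])[:100]
    tag = clip_adapter(read, DEFAULT_ADAPTER, min_match=8)
    shown = tag.inferred_length if not tag.unmeasured else "unmeasured (>= 93)"
    print(f"insert {insert_len:3d} nt -> inferred length: {shown} "
          f"(adapter bases matched: {tag.adapter_match})")

first_fail = next(
    L for L in range(101)
    if clip_adapter((fill[:L] + DEFAULT_ADAPTER + fill[::-1])[:100]).unmeasured
)
print(f"\nfirst insert length with no detectable adapter: {first_fail} nt")
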