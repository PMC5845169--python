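"""FASTQ input helpers (gzip-aware via pysam)."""

from __future__ import annotations

from typing import Iterator

import pysam

from .demux import ReadRecord

__all__ = ["read_paired_fastq"]


def read_paired_fastq(r1_path, r2_path=None, i1_path=None) -> Iterator[ReadRecord]:
    """Stream paired FASTQ files into :class:`ReadRecord` objects.

    Files must be record-aligned; read-id mismatches raise immediately.
    """
    r1 = pysam.FastxFile(str(r1_path))
    r2 = pysam.FastxFile(str(r2_path)) if r2_path else None
    i1 = pysam.FastxFile(str(i1_path)) if i1_path else None
    try:
        for rec1 in r1:
            rec2 = next(r2) if r2 else None
            rec_i = next(i1) if i1 else None
            for other in (rec2, rec_i):
                if other is not None and other.name != rec1.name:
                    raise ValueError(
                        f"FASTQ files out of sync: {rec1.name} vs {other.name}"
                    )
            yield ReadRecord(
                read_id=rec1.name,
                read1_seq=rec1.sequence,
                read1_qual=tuple(rec1.get_quality_array()) if rec1.quality else None,
                index1_seq=rec_i.sequence if rec_i else None,
                read2_seq=rec2.sequence if rec2 else None,
            )
    finally:
        r1.close()
        if r2:
            r2.close()
        if i1:
            i1.close()
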