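"""Independent brute-force reference for word-level reading measures.

Deliberately naive: for every word it rescans the whole fixation sequence
with Python lists, following the measure definitions word by word.  Used as
the oracle against the vectorized implementation.
"""

import math


def brute_force_measures(word_index, duration, n_words):
    """Return a list of dicts, one per word, with the seven measures."""
    seq = list(zip(list(word_index), list(duration)))
    out = []
    for w in range(n_words):
        fix_times = [t for t, (wi, _) in enumerate(seq) if wi == w]
        n_fix = len(fix_times)
        tft = sum(d for wi, d in seq if wi == w)
        ffd = fprt = rpd = fpreg = math.nan
        if fix_times:
            t0 = fix_times[0]
            fixated_before = [wi for wi, _ in seq[:t0]]
            if all(wi <= w for wi in fixated_before):
                # first pass: consecutive run on w starting at t0
                t_end = t0
                while t_end + 1 < len(seq) and seq[t_end + 1][0] == w:
                    t_end += 1
                ffd = seq[t0][1]
                fprt = sum(d for _, d in seq[t0 : t_end + 1])
                if t_end + 1 < len(seq):
                    fpreg = 1.0 if seq[t_end + 1][0] < w else 0.0
                else:
                    fpreg = 0.0
                exits = [
                    t for t in range(t0, len(seq)) if seq[t][0] > w
                ]
                t_exit = exits[0] if exits else len(seq)
                rpd = sum(d for _, d in seq[t0:t_exit])
        out.append(
            {
                "word_index": w,
                "FFD": ffd,
                "FPRT": fprt,
                "RPD": rpd,
                "TFT": float(tft),
                "FPReg": fpreg,
                "SKIP": int(n_fix == 0),
                "N_FIX": n_fix,
            }
        )
    return out
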