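"""Independent index-by-index reference implementations used as oracles."""

import numpy as np


def naive_features(vals, latency, peak, cfg):
    """Index-by-index reference implementation of all 86 features.

    Deliberately plain Python: scalar loops, direct index arithmetic,
    independent of the vectorized implementation it checks.
    """
    fps = cfg.fps
    n = len(vals)

    def at(idx):
        idx = min(int(idx), n - 1)
        return vals[max(idx, 0)]

    def f2i(sec):
        return int(round(sec * fps))

    def anchors(lat):
        lat = min(max(int(lat), 0), peak - 1)
        ttp = (peak - lat) / fps
        upslope = (1.0 - at(lat)) / ttp if ttp > 0 else float("nan")
        half = peak
        for i in range(lat, peak + 1):
            if vals[i] >= 0.5 * vals[peak]:
                half = i
                break
        t_half = (half - lat) / fps
        tr = ttp / t_half if t_half > 0 else float("nan")
        return ttp, upslope, tr, half

    out = {}
    ttp, upslope, tr, half = anchors(latency)
    out["TTP_rel"], out["U_rel"], out["TR_rel"] = ttp, upslope, tr
    for s in cfg.s_set:
        out[f"D{s:g}_rel"] = (1.0 - at(peak + f2i(s))) / s
        out[f"HIF{s:g}_rel"] = (1.0 - at(half + f2i(s))) / s

    ttps, ups, trs = [], [], []
    for off in cfg.window_offsets:
        a = anchors(latency + f2i(off))
        ttps.append(a[0])
        ups.append(a[1])
        trs.append(a[2])

    def nanmedian(xs):
        xs = [x for x in xs if x == x]
        return float(np.median(xs)) if xs else float("nan")

    out["TTP_avg"] = nanmedian(ttps)
    out["U_avg"] = nanmedian(ups)
    out["TR_avg"] = nanmedian(trs)
    for s in cfg.s_set:
        dvals, hvals = [], []
        for off in cfg.window_offsets:
            se = s + off
            if se <= 0:
                continue
            dvals.append((1.0 - at(peak + f2i(se))) / se)
            hvals.append((1.0 - at(half + f2i(se))) / se)
        out[f"D{s:g}_avg"] = float(np.median(dvals))
        out[f"HIF{s:g}_avg"] = float(np.median(hvals))
    return out
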