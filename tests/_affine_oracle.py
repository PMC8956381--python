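"""Brute-force affine-gap semi-global alignment score, written as an
independent oracle: a plain three-matrix Gotoh recurrence with explicit
free reference end-gaps, no vectorization, no shared code with the package
aligner. A gap of length L costs open + (L - 1) * extend; leading/trailing
unaligned reference is free; query end overhangs are charged normally."""

NEG = float("-inf")


def affine_semiglobal_score(query, reference, match=1.0, mismatch=-1.0,
                            gap_open=-4.0, gap_extend=-1.0):
    q, r = query.upper(), reference.upper()
    m, n = len(q), len(r)

    def sub(a, b):
        return match if a == b else mismatch

    # M[i][j]: ref[:i] vs q[:j] ending in an aligned pair
    # D[i][j]: ending in a gap in the query row (ref base unaligned, internal)
    # I[i][j]: ending in a gap in the reference row (query base unaligned)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    I = [[NEG] * (m + 1) for _ in range(n + 1)]
    # free reference prefix: alignment of the query may start after any i
    F = [0.0] * (n + 1)

    for j in range(1, m + 1):
        # query-only prefix (insertion before any reference is consumed)
        I[0][j] = (gap_open if j == 1 else I[0][j - 1] + gap_extend)
    for i in range(1, n + 1):
        I[i][0] = NEG
        for j in range(1, m + 1):
            prev = max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
            if j == 1:
                prev = max(prev, F[i - 1])
            M[i][j] = prev + sub(r[i - 1], q[j - 1]) if prev > NEG else NEG
            best_d = max(
                M[i - 1][j] + gap_open if M[i - 1][j] > NEG else NEG,
                I[i - 1][j] + gap_open if I[i - 1][j] > NEG else NEG,
                D[i - 1][j] + gap_extend if D[i - 1][j] > NEG else NEG,
            )
            D[i][j] = best_d
            best_i = max(
                M[i][j - 1] + gap_open if M[i][j - 1] > NEG else NEG,
                D[i][j - 1] + gap_open if D[i][j - 1] > NEG else NEG,
                I[i][j - 1] + gap_extend if I[i][j - 1] > NEG else NEG,
            )
            if j == 1:
                best_i = max(best_i, F[i] + gap_open)
            I[i][j] = best_i

    # free reference suffix: stop after any i once the query is consumed.
    # An alignment ending in a query-row gap run merges into the free
    # suffix, so D-endings are equivalent to stopping earlier.
    best = max(max(M[i][m], I[i][m]) for i in range(n + 1))
    if m == 0:
        best = 0.0
    return best
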