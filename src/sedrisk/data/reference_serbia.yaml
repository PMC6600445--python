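# Reference values for the Serbian river-sediment study (mg/kg dry weight).
# background: local background concentration C_n (study minima); null = not established.
# toxic_response: Hakanson toxic response factor T_r (dimensionless); null = not assigned.
# guideline: Serbian sediment guideline value; null = none published.
# Elements with a null background or toxic_response are excluded from Er/RI
# with an explicit report; they are never silently imputed.
elements:
  Cd: {background: 1.28, toxic_response: 30, guideline: 3}
  Co: {background: 8.22, toxic_response: null, guideline: null}
  Cr: {background: 62.1, toxic_response: 2, guideline: 100}
  Cu: {background: 11.5, toxic_response: 5, guideline: 100}
  Fe: {background: 24556, toxic_response: null, guideline: null}
  Mn: {background: 648, toxic_response: null, guideline: null}
  Ni: {background: null, toxic_response: 5, guideline: 50}
  Pb: {background: 57.8, toxic_response: 5, guideline: 100}
  V: {background: 66.4, toxic_response: null, guideline: null}
  Zn: {background: 66.6, toxic_response: 1, guideline: 300}
  As: {background: null, toxic_response: 10, guideline: 25}
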