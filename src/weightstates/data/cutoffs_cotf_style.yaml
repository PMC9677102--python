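provenance: cotf_style
note: synthetic fixture table with plausible shape; not official reference values
entries:
- sex: girl
  age_lo: 3.0
  age_hi: 4.0
  c_ow: 16.37
  c_ob: 17.67
- sex: girl
  age_lo: 4.0
  age_hi: 5.0
  c_ow: 16.22
  c_ob: 17.52
- sex: girl
  age_lo: 5.0
  age_hi: 6.0
  c_ow: 16.22
  c_ob: 17.66
- sex: girl
  age_lo: 6.0
  age_hi: 7.0
  c_ow: 16.37
  c_ob: 18.09
- sex: girl
  age_lo: 7.0
  age_hi: 8.0
  c_ow: 16.67
  c_ob: 18.67
- sex: girl
  age_lo: 8.0
  age_hi: 9.0
  c_ow: 17.12
  c_ob: 19.4
- sex: girl
  age_lo: 9.0
  age_hi: 10.0
  c_ow: 17.72
  c_ob: 20.28
- sex: girl
  age_lo: 10.0
  age_hi: 11.0
  c_ow: 18.47
  c_ob: 21.31
- sex: girl
  age_lo: 11.0
  age_hi: 12.0
  c_ow: 19.37
  c_ob: 22.49
- sex: girl
  age_lo: 12.0
  age_hi: 20.0
  c_ow: 22.28
  c_ob: 26.1
- sex: boy
  age_lo: 3.0
  age_hi: 4.0
  c_ow: 16.77
  c_ob: 18.07
- sex: boy
  age_lo: 4.0
  age_hi: 5.0
  c_ow: 16.62
  c_ob: 17.92
- sex: boy
  age_lo: 5.0
  age_hi: 6.0
  c_ow: 16.62
  c_ob: 18.06
- sex: boy
  age_lo: 6.0
  age_hi: 7.0
  c_ow: 16.77
  c_ob: 18.49
- sex: boy
  age_lo: 7.0
  age_hi: 8.0
  c_ow: 17.07
  c_ob: 19.07
- sex: boy
  age_lo: 8.0
  age_hi: 9.0
  c_ow: 17.52
  c_ob: 19.8
- sex: boy
  age_lo: 9.0
  age_hi: 10.0
  c_ow: 18.12
  c_ob: 20.68
- sex: boy
  age_lo: 10.0
  age_hi: 11.0
  c_ow: 18.87
  c_ob: 21.71
- sex: boy
  age_lo: 11.0
  age_hi: 12.0
  c_ow: 19.77
  c_ob: 22.89
- sex: boy
  age_lo: 12.0
  age_hi: 20.0
  c_ow: 22.68
  c_ob: 26.5
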