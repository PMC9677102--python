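provenance: who_style
note: synthetic fixture table with plausible shape; not official reference values
entries:
- sex: girl
  age_lo: 3.0
  age_hi: 4.0
  c_ow: 16.15
  c_ob: 17.6
- sex: girl
  age_lo: 4.0
  age_hi: 5.0
  c_ow: 15.97
  c_ob: 17.42
- sex: girl
  age_lo: 5.0
  age_hi: 6.0
  c_ow: 15.97
  c_ob: 17.53
- sex: girl
  age_lo: 6.0
  age_hi: 7.0
  c_ow: 16.15
  c_ob: 17.93
- sex: girl
  age_lo: 7.0
  age_hi: 8.0
  c_ow: 16.51
  c_ob: 18.51
- sex: girl
  age_lo: 8.0
  age_hi: 9.0
  c_ow: 17.05
  c_ob: 19.27
- sex: girl
  age_lo: 9.0
  age_hi: 10.0
  c_ow: 17.77
  c_ob: 20.21
- sex: girl
  age_lo: 10.0
  age_hi: 11.0
  c_ow: 18.67
  c_ob: 21.33
- sex: girl
  age_lo: 11.0
  age_hi: 12.0
  c_ow: 19.75
  c_ob: 22.63
- sex: girl
  age_lo: 12.0
  age_hi: 20.0
  c_ow: 23.24
  c_ob: 26.67
- sex: boy
  age_lo: 3.0
  age_hi: 4.0
  c_ow: 16.5
  c_ob: 17.95
- sex: boy
  age_lo: 4.0
  age_hi: 5.0
  c_ow: 16.32
  c_ob: 17.77
- sex: boy
  age_lo: 5.0
  age_hi: 6.0
  c_ow: 16.32
  c_ob: 17.88
- sex: boy
  age_lo: 6.0
  age_hi: 7.0
  c_ow: 16.5
  c_ob: 18.28
- sex: boy
  age_lo: 7.0
  age_hi: 8.0
  c_ow: 16.86
  c_ob: 18.86
- sex: boy
  age_lo: 8.0
  age_hi: 9.0
  c_ow: 17.4
  c_ob: 19.62
- sex: boy
  age_lo: 9.0
  age_hi: 10.0
  c_ow: 18.12
  c_ob: 20.56
- sex: boy
  age_lo: 10.0
  age_hi: 11.0
  c_ow: 19.02
  c_ob: 21.68
- sex: boy
  age_lo: 11.0
  age_hi: 12.0
  c_ow: 20.1
  c_ob: 22.98
- sex: boy
  age_lo: 12.0
  age_hi: 20.0
  c_ow: 23.59
  c_ob: 27.02
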