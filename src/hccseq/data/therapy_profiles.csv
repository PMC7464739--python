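treatment,line,median_months,iqr_months,sae_pct
Sorafenib,first,4.6,6.7,72.3
Lenvatinib,first,8.8,11.7,75.0
Atezolizumab plus Bevacizumab,first,7.2,9.3,61.0
Regorafenib,second,11.4,14.4,79.7
Cabozantinib,second,11.4,14.0,79.4
Ramucirumab,second,11.3,14.5,70.4
Nivolumab,second,16.4,23.2,18.6
Pembrolizumab,second,14.0,17.8,52.7
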