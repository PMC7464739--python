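sequence,first_line,second_line,median_os_mo,nnt,os36_pct,lyg_yr,sae_pct
Lenvatinib-Nivolumab,Lenvatinib,Nivolumab,27,5,32.9,0.75,48.0
Lenvatinib-Pembrolizumab,Lenvatinib,Pembrolizumab,25,7,26.8,0.58,64.4
Atezolizumab plus Bevacizumab-Nivolumab,Atezolizumab plus Bevacizumab,Nivolumab,24,6,29.5,0.50,40.2
Sorafenib-Nivolumab,Sorafenib,Nivolumab,23,7,26.1,0.42,46.3
Atezolizumab plus Bevacizumab-Pembrolizumab,Atezolizumab plus Bevacizumab,Pembrolizumab,23,9,23.4,0.42,57.1
Lenvatinib-Ramucirumab,Lenvatinib,Ramucirumab,22,13,19.9,0.33,72.8
Lenvatinib-Regorafenib,Lenvatinib,Regorafenib,22,14,19.3,0.33,77.2
Lenvatinib-Cabozantinib,Lenvatinib,Cabozantinib,22,14,19.2,0.33,77.2
Sorafenib-Pembrolizumab,Sorafenib,Pembrolizumab,20,15,18.9,0.17,62.9
Atezolizumab plus Bevacizumab-Ramucirumab,Atezolizumab plus Bevacizumab,Ramucirumab,20,23,16.7,0.17,65.6
Atezolizumab plus Bevacizumab-Regorafenib,Atezolizumab plus Bevacizumab,Regorafenib,20,29,15.8,0.17,70.0
Atezolizumab plus Bevacizumab-Cabozantinib,Atezolizumab plus Bevacizumab,Cabozantinib,20,30,15.6,0.17,69.9
Sorafenib-Cabozantinib,Sorafenib,Cabozantinib,18,83,11.1,0.00,75.8
Sorafenib-Regorafenib,Sorafenib,Regorafenib,18,200,11.8,0.00,75.9
Sorafenib-Ramucirumab,Sorafenib,Ramucirumab,18,-,12.3,0.00,71.4
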