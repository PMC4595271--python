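region,year,phenophase,days,rad_kj_m2,gdd,sunshine_h,rainfall_mm,temp_diff_c
CL,2011,Flowering,13,31508,127.70,132.00,3.50,11.39
CL,2011,Berry development,48,110124,575.30,250.70,181.10,6.42
CL,2011,Veraison,24,46340,353.40,101.60,342.70,5.60
CL,2011,Ripening,36,69717,394.00,290.70,28.00,9.73
GT,2011,Flowering,7,12253,99.90,64.10,0.00,16.10
GT,2011,Berry development,53,81898,739.00,525.30,25.70,14.60
GT,2011,Veraison,17,28011,180.70,126.90,48.80,12.70
GT,2011,Ripening,25,38491,191.00,221.70,6.40,13.30
CL,2010,Flowering,5,11537,47.40,55.80,0.00,10.40
CL,2010,Berry development,51,87562,671.80,320.70,162.90,6.60
CL,2010,Veraison,20,30430,232.10,106.90,219.50,6.70
CL,2010,Ripening,34,43105,363.80,182.40,159.70,7.90
GT,2010,Flowering,6,17608,87.10,79.30,0.00,17.60
GT,2010,Berry development,62,138144,884.10,612.60,32.60,14.30
GT,2010,Veraison,16,34442,178.80,168.20,9.40,15.82
GT,2010,Ripening,25,34589,142.10,161.20,65.70,11.50
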