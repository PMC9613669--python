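unit,level,parent,year,median
Adamawa,region,National,2000,137484
Adamawa,region,National,2010,184659
Adamawa,region,National,2020,252072
Adamawa,region,National,2030,348829
Centre,region,National,2000,337354
Centre,region,National,2010,504928
Centre,region,National,2020,786405
Centre,region,National,2030,1264514
East,region,National,2000,109582
East,region,National,2010,134833
East,region,National,2020,167296
East,region,National,2030,208402
Far North,region,National,2000,495044
Far North,region,National,2010,633579
Far North,region,National,2020,818946
Far North,region,National,2030,1069814
Littoral,region,National,2000,283893
Littoral,region,National,2010,400442
Littoral,region,National,2020,576482
Littoral,region,National,2030,841799
North,region,National,2000,272069
North,region,National,2010,419150
North,region,National,2020,662131
North,region,National,2030,1066891
Northwest,region,National,2000,164941
Northwest,region,National,2010,206518
Northwest,region,National,2020,265193
Northwest,region,National,2030,350104
West,region,National,2000,227774
West,region,National,2010,266688
West,region,National,2020,321025
West,region,National,2030,396079
South,region,National,2000,74957
South,region,National,2010,110865
South,region,National,2020,167628
South,region,National,2030,258435
Southwest,region,National,2000,157567
Southwest,region,National,2010,194928
Southwest,region,National,2020,247275
Southwest,region,National,2030,319614
National,national,,2000,2260665
National,national,,2010,3056589
National,national,,2020,4264453
National,national,,2030,6124480
Mfoundi,division,Centre,2030,1019032
Wouri,division,Littoral,2030,749306
Benoue,division,North,2030,706967
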