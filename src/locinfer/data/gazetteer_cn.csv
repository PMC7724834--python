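level,canonical_name,parent_province,aliases
province,北京,,北京市
province,天津,,天津市
province,上海,,上海市
province,重庆,,重庆市
province,河北,,河北省
province,山西,,山西省
province,辽宁,,辽宁省
province,吉林,,吉林省
province,黑龙江,,黑龙江省
province,江苏,,江苏省
province,浙江,,浙江省
province,安徽,,安徽省
province,福建,,福建省
province,江西,,江西省
province,山东,,山东省
province,河南,,河南省
province,湖北,,湖北省
province,湖南,,湖南省
province,广东,,广东省
province,海南,,海南省
province,四川,,四川省
province,贵州,,贵州省
province,云南,,云南省
province,陕西,,陕西省
province,甘肃,,甘肃省
province,青海,,青海省
province,台湾,,台湾省
province,内蒙古,,内蒙古自治区
province,广西,,广西壮族自治区
province,西藏,,西藏自治区
province,宁夏,,宁夏回族自治区
province,新疆,,新疆维吾尔自治区
province,香港,,香港特别行政区
province,澳门,,澳门特别行政区
city,北京,北京,北京市
city,天津,天津,天津市
city,上海,上海,上海市
city,重庆,重庆,重庆市
city,香港,香港,香港特别行政区
city,澳门,澳门,澳门特别行政区
city,石家庄,河北,石家庄市
city,唐山,河北,唐山市
city,保定,河北,保定市
city,秦皇岛,河北,秦皇岛市
city,太原,山西,太原市
city,大同,山西,大同市
city,沈阳,辽宁,沈阳市
city,大连,辽宁,大连市
city,长春,吉林,长春市
city,哈尔滨,黑龙江,哈尔滨市
city,大庆,黑龙江,大庆市
city,南京,江苏,南京市
city,苏州,江苏,苏州市
city,无锡,江苏,无锡市
city,徐州,江苏,徐州市
city,南通,江苏,南通市
city,常州,江苏,常州市
city,连云港,江苏,连云港市
city,杭州,浙江,杭州市
city,宁波,浙江,宁波市
city,温州,浙江,温州市
city,嘉兴,浙江,嘉兴市
city,合肥,安徽,合肥市
city,芜湖,安徽,芜湖市
city,福州,福建,福州市
city,厦门,福建,厦门市
city,泉州,福建,泉州市
city,南昌,江西,南昌市
city,赣州,江西,赣州市
city,济南,山东,济南市
city,青岛,山东,青岛市
city,烟台,山东,烟台市
city,潍坊,山东,潍坊市
city,郑州,河南,郑州市
city,洛阳,河南,洛阳市
city,开封,河南,开封市
city,武汉,湖北,武汉市
city,宜昌,湖北,宜昌市
city,襄阳,湖北,襄阳市
city,长沙,湖南,长沙市
city,株洲,湖南,株洲市
city,湘潭,湖南,湘潭市
city,衡阳,湖南,衡阳市
city,广州,广东,广州市
city,深圳,广东,深圳市
city,珠海,广东,珠海市
city,佛山,广东,佛山市
city,东莞,广东,东莞市
city,中山,广东,中山市
city,惠州,广东,惠州市
city,海口,海南,海口市
city,三亚,海南,三亚市
city,成都,四川,成都市
city,绵阳,四川,绵阳市
city,南充,四川,南充市
city,宜宾,四川,宜宾市
city,贵阳,贵州,贵阳市
city,遵义,贵州,遵义市
city,昆明,云南,昆明市
city,大理,云南,大理市
city,丽江,云南,丽江市
city,西安,陕西,西安市
city,咸阳,陕西,咸阳市
city,宝鸡,陕西,宝鸡市
city,兰州,甘肃,兰州市
city,天水,甘肃,天水市
city,西宁,青海,西宁市
city,呼和浩特,内蒙古,呼和浩特市
city,包头,内蒙古,包头市
city,南宁,广西,南宁市
city,桂林,广西,桂林市
city,柳州,广西,柳州市
city,拉萨,西藏,拉萨市
city,银川,宁夏,银川市
city,乌鲁木齐,新疆,乌鲁木齐市
city,喀什,新疆,喀什市
city,台北,台湾,台北市
city,高雄,台湾,高雄市
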